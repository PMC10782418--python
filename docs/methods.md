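# Methods

## Spectra as discrete measures

A 1-D ¹H NMR spectrum is represented as a discrete measure on the
chemical shift axis: a finite set of (ppm, intensity) pairs.  After
normalization (division by the total intensity) it is a probability
measure.  Nothing is assumed about the axis beyond ordering — the
mixture and every library component may carry their own grid, range and
point count, which is what lets a high-field library be fitted against a
benchtop mixture spectrum.  Duplicate shift values are merged by summing
mass; negative intensities (baseline and phase artifacts) are clipped to
zero with a warning before normalization, since a signed "measure" has
no transport interpretation and the method is designed to need little
other preprocessing.  Solvent regions can be excluded with explicit
`trim_ranges`; no region is trimmed by default.

## Wasserstein-1 distance

The dissimilarity between two normalized spectra μ and ν is the
Wasserstein-1 (earth mover's) distance: the minimum of
Σ γ(x,y)·|x−y| over all couplings γ with marginals μ and ν.  On the
real line this has a closed form — the integral of |F_μ − F_ν| between
the cumulative distribution functions — evaluated here exactly on the
merged support in O(n) after sorting.  The optimal coupling itself is
the monotone (sorted-merge) plan, which the package materializes
explicitly so that the flow of signal can be inspected and serialized.
W1 is insensitive to resolution differences and degrades gracefully
under peak drift (a rigid shift by δ costs exactly |δ|), which is the
property the whole estimator is built on.

## The deconvolution model

Given a library ν₁…ν_k, the composition is estimated by Wasserstein
regression: minimize W(μ, ν_p) over the simplex, ν_p = Σ pᵢνᵢ.  Real
spectra contain signal the model cannot explain, on both sides:

* contaminants and noise in the mixture;
* excess or missing resonances in experimentally acquired library
  spectra.

Both sides are therefore augmented with an off-axis sink ("vortex")
conceptually equidistant κ from every on-axis position.  Mixture signal
may be routed to ω at per-unit cost `kappa_mixture` (total removed
fraction p₀, with Σpᵢ + p₀ = 1), and library signal to ξ at per-unit
cost `kappa_components` (fraction p₀′, with the mixture side scaled by
1 − p₀′).  The estimator minimizes

    W( p₀′·ξ + (1 − p₀′)·μ ,  p₀·ω + ν_p )

jointly over p, p₀, p₀′.  Each κ acts as the largest chemical shift
mismatch at which signal is still matched rather than discarded: a
resonance farther than κ from any counterpart is cheaper to remove.
Unlike bin-based peak matching, the decision is global — whether a
signal is removed depends on the whole distribution, not on a local
window — which is why one pair of defaults covers very different
experiments.

Defaults: `kappa_mixture = 0.25 ppm`, `kappa_components = 0.22 ppm`.
Reported composition is p / Σp (proportions of the *explained* signal);
the raw p, p₀ and p₀′ are returned alongside.

## Linear program

Because the ground cost is |x−y|, on-axis transport decomposes into
signed flows on the segments of the merged support grid x₁<…<x_m:
cost Σ_j |z_j|·(x_{j+1}−x_j).  The LP variables are the proportions
pᵢ ≥ 0, the mixture scale t = 1 − p₀′ (one scalar, which keeps every
constraint row sparse), per-node removals a_j (mixture → ω) and b_j
(ξ → library), and the positive/negative parts of each segment flow.
Constraints: flow conservation at each node,
Σpᵢ + Σa_j = 1, t + Σb_j = 1, and removal caps
a_j ≤ t·μ(x_j), b_j ≤ Σᵢ pᵢνᵢ(x_j).  Direct ω↔ξ transport is excluded:
a finite ω–ξ arc cheaper than κ_mixture + κ_components would let
matched mass be discarded from both sides at a discount (at cost zero
it makes p₀ = p₀′ = 1 free), breaking the stated removal prices.

This is O(m + k) variables and O(m) constraints, solved with the HiGHS
dual simplex (`scipy.optimize.linprog`, feasibility/optimality
tolerances 1e-9).  The trivial all-removal solution is always feasible,
so a clean optimum exists for every valid input; results violating the
mass-balance or plan-cost invariants by more than 1e-7 raise rather
than return.  Correctness is established against an independent dense
formulation — one transport variable per (mixture point, library point)
pair plus explicit vortex arcs — on small random instances, where the
two optima agree to ~1e-15.

For degenerate libraries (duplicate or collinear components) the solver
returns one optimal vertex; no uniqueness detection is attempted, and
only objective-value equality with the oracle is guaranteed.

## Error metrics and conversions

* `l1_error` = Σᵢ |p_est,i − p_true,i| (the heat-map error of the
  penalty sweep);
* RE_i = |p_est,i − p_true,i| / p_true,i, AvRE = mean(RE), in percent;
* signal → molar proportions: divide by per-compound proton counts and
  renormalize (not applied by default — reported proportions are signal
  fractions);
* absolute concentrations via an external standard added to the mixture
  and present in the library: cᵢ = c_ref · (pᵢ/Hᵢ)/(p_ref/H_ref).

## Synthetic scenarios

The generator emulates the geometric challenges of real mixture
analysis, not the spin physics: components are sums of area-weighted
Lorentzian/Gaussian lines evaluated on a uniform grid; mixtures are
exact convex combinations passed through an ordered list of corruption
operators (uniform shift; Lorentzian-kernel broadening, mass-conserving;
coarse re-binning; contaminant admixture; non-negative folded-normal
noise, so normalization semantics survive without clipping; sinusoidal
position warp emulating per-peak drift).  All randomness flows from
explicit seeds.

Five presets mirror classic failure modes, with problem sizes chosen so
one deconvolution runs in a few seconds on one CPU core:

| preset | challenge | conditions |
|---|---|---|
| exp1 | intensity imbalance | 2 terpene/ester analogues at 9:91, 3500-pt grid |
| exp2 | contamination | 2 overlapping terpene analogues 50:50 + 3% foreign peaks |
| exp3 | low resolution | 4 components, 0.06-ppm linewidths, mixture re-binned 4096→1024 |
| exp4 | lineshape distortion | 5 crowded metabolite analogues, mixture broadened 4× |
| exp5 | peak drift | 5 spread metabolite analogues, +0.03 ppm shift + 0.005 ppm warp |

Two deliberate geometry choices:

* **exp4 (crowded layout).**  CH₃ analogues 0.15 ppm apart and N-CH₃
  singlets 0.02 ppm apart reproduce the lactate/alanine and
  creatine/creatinine near-degeneracies; broadening, not drift, is the
  challenge, so near-coincident peaks are fair.
* **exp5 (spread layout).**  Identifiability under a rigid drift δ
  requires distinct compounds' resonances to be separated by more than
  2δ — past that point a drifted peak is genuinely closer to a
  neighbour's library position and *no* method can attribute it.  The
  drift scenario therefore uses a layout with all cross-component
  spacings ≥ 0.3 ppm, supporting drifts up to ~0.1 ppm.  The warp
  amplitude (0.005 ppm) reflects that per-compound differences in
  temperature coefficients are an order of magnitude smaller than the
  bulk drift.

What passing these benchmarks shows — and does not.  The synthetic
mixtures are exact convex combinations plus controlled corruption; real
spectra add J-coupling structure, baseline roll, solvent artifacts and
concentration-dependent shifts that the generator does not model.  The
presets demonstrate that the estimator survives each geometric failure
mode in isolation at the default penalties; they are not a substitute
for validation on acquired spectra.

## Numerical choices and edge cases

* Grids are merged exactly (float equality); `max_grid` optionally
  coarsens every input first.  Coarsening bins points into equal-width
  ppm bins, each replaced by its center of mass, so total mass is exact
  and the W1 displacement is at most half a bin width.
* Removal caps make a_j, b_j vanish wherever the corresponding side has
  no mass; ties between matching and removal at exactly distance κ are
  resolved by the solver arbitrarily (tests use strictly larger or
  smaller distances).
* `deconvolve_unpenalized` solves the plain regression directly (no
  vortex variables); with both κ above the axis span the penalized
  problem reduces to it, which is verified numerically.
* Very small `kappa_components` is degenerate by design: once it drops
  below the achievable matching cost, discarding the *entire* library
  side (p₀′ = 1, mixture scale t = 0) is optimal and the composition
  estimate is meaningless.  The penalty sweep makes this visible as an
  l1_error cliff; both defaults sit far from the cliff.
* Lorentzian tails mean a "far" contaminant still leaves ~1% of its
  mass near library peaks; the exact p₀ = fraction identity holds for
  compact (Gaussian) contaminants and is asserted at 1e-3 tolerance.

## Known limitations

* 1-D spectra only; the segment-flow reduction of W1 has no
  higher-dimensional analogue.
* No peak picking, lineshape fitting, phase/baseline correction or
  alignment — inputs are expected to be magnitude-correct intensity
  tables.
* The JCAMP-DX reader covers uncompressed XYPOINTS / PEAK TABLE /
  AFFN XYDATA records only.
* Proportions are signal fractions; molar interpretation requires
  correct proton counts supplied by the user.
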