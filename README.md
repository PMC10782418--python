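# otnmr — quantitative NMR mixture analysis by optimal transport

`otnmr` estimates the composition of a mixture from its 1-D ¹H NMR
spectrum and a library of component spectra.  Instead of picking peaks
and matching peak lists — which breaks down at low resolution, under
lineshape distortion, and when chemical shifts drift between library
and mixture — it treats every spectrum as a discrete probability
measure on the ppm axis and fits the mixture with the combination of
library spectra that is closest in Wasserstein (earth mover's)
distance.

It is intended for analytical chemists and metabolomics/qNMR
practitioners quantifying known components in crowded spectra,
including benchtop (low-field) data, and for method developers who want
a transparent, fully testable optimal-transport baseline.

## Model

Given a mixture spectrum μ and normalized library spectra ν₁…ν_k, the
estimator solves

    min  W( p₀′·ξ + (1 − p₀′)·μ ,  p₀·ω + Σᵢ pᵢνᵢ )
    over pᵢ ≥ 0,  Σᵢ pᵢ + p₀ = 1,  p₀′ ∈ [0, 1]

where W is the Wasserstein-1 distance with ground cost |x − y| in ppm,
and ω, ξ are off-axis sinks ("vortices") at distance `kappa_mixture`
(default 0.25 ppm) and `kappa_components` (default 0.22 ppm) from every
on-axis position.  Mass sent to ω is mixture signal the library cannot
explain (fraction p₀: contaminants, noise); mass drawn from ξ covers
library signal missing from the mixture (fraction p₀′).  Each κ is the
largest shift mismatch at which signal is still matched rather than
discarded.  The problem is solved exactly as a sparse linear program
(segment flows on the merged grid; HiGHS dual simplex), and the
reported composition is p / Σp.  See `docs/methods.md` for the full
formulation, numerical choices and limitations.

## Worked example

`examples/contaminant_denoising.py` spikes a 40:60 two-component
mixture with 15% foreign signal far from all library resonances:

```text
contaminant fraction injected : 0.150
p0 recovered by the estimator : 0.1500
reported proportions          : (0.4, 0.6)
true proportions              : [0.4, 0.6]
AvRE                          : 0.00%
```

The vortex absorbs exactly the injected contaminant mass (p₀ = 0.15 at
cost 0.25/unit, cheaper than transporting it to a distant library
peak), so the composition estimate is unbiased.  AvRE is the mean over
components of |p_est − p_true| / p_true.

`examples/challenge_benchmarks.py` runs the five built-in synthetic
challenge presets at the default penalties:

```text
preset challenge                             AvRE       p0  p0_prime   time
exp1   1:10 intensity imbalance             0.46%   0.0024    0.0000   1.9s
exp2   peak overlap + contaminant           0.07%   0.0329    0.0000   1.6s
exp3   low resolution, heavy overlap        1.16%   0.0043    0.0000   2.8s
exp4   lineshape distortion (bad shim)      2.56%   0.0150    0.0000   3.2s
exp5   peak position drift                  0.75%   0.0022    0.0005   6.1s
```

The other examples cover the file-based workflow
(`quantify_two_component.py`), penalty tuning (`kappa_sweep.py`) and
absolute quantification with an external standard
(`absolute_concentration.py`).

## Command line

```bash
otnmr quantify --mixture mix.csv --component limonene=lim.csv \
      --component pinene=pin.csv --kappa-mixture 0.25 \
      --kappa-components 0.22 --out result.json

otnmr simulate --preset exp3 --seed 1 --out simdir/

otnmr sweep --mixture mix.csv --component a=a.csv --component b=b.csv \
      --km-grid 0.05,0.25,1.0 --kc-grid 0.05,0.22,1.0 \
      --truth simdir/truth.json --out grid.csv
```

Spectra are two-column delimited text (ppm, intensity; `#` comments;
either axis direction); a minimal uncompressed JCAMP-DX reader is also
available from the library API.  Results are JSON; penalty sweeps and
transport plans are CSV.

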