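"""Wasserstein deconvolution of mixture spectra.

The estimator treats quantification as regression under an optimal
transport loss.  Given a mixture spectrum ``mu`` and a library of
normalized component spectra ``nu_1 .. nu_k``, it seeks proportions
``p_1 .. p_k`` minimizing the Wasserstein distance between the mixture
and the combination ``nu_p = sum_i p_i nu_i``.  Real spectra carry signal
the model cannot explain — contaminants and noise in the mixture, excess
or missing resonances in experimentally acquired library spectra — so
both sides are augmented with an off-axis sink: mixture signal may be
routed to a vortex ``omega`` at cost ``kappa_mixture`` per unit mass
(total removed fraction ``p0``), and library signal to a vortex ``xi`` at
cost ``kappa_components`` per unit mass (fraction ``p0_prime``).  The
optimum therefore simultaneously estimates the composition and labels
the unexplained signal on both sides.

Because the cost on the chemical shift axis is ``|x - y|``, transport
between axis positions can be expressed with one signed flow variable
per gap of the merged support grid, which keeps the linear program sparse:
``O(m + k)`` variables and ``O(m)`` constraints for ``m`` grid points.
It is solved with the HiGHS dual simplex via :func:`scipy.optimize.linprog`.
A dense oracle formulation (:func:`deconvolve_oracle`) with one variable
per support pair provides an independent check on small instances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .spectra import ComponentLibrary, Spectrum, SpectrumError, coarsen
from .transport import OMEGA, XI, TransportPlan, _monotone_entries

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "SolverError",
    "deconvolve",
    "deconvolve_unpenalized",
    "deconvolve_oracle",
    "estimation_errors",
    "EstimationErrors",
    "signal_to_molar",
    "absolute_concentrations",
    "parameter_sweep",
    "result_to_dict",
    "result_to_json",
]


class SolverError(RuntimeError):
    """The linear program did not reach a clean optimum."""


@dataclass(frozen=True)
class DeconvolutionConfig:
    """Tunable parameters of the estimator.

    ``kappa_mixture`` and ``kappa_components`` are the per-unit-mass
    removal costs (in ppm) for mixture and library signal respectively.
    Each acts as the largest frequency mismatch up to which a signal is
    still matched rather than discarded: signal farther than kappa from
    any counterpart is cheaper to remove.  The defaults work across a
    broad range of experiments.

    ``max_grid`` optionally caps the support size of every input spectrum
    via :func:`otnmr.spectra.coarsen` before the LP is built.
    """

    kappa_mixture: float = 0.25
    kappa_components: float = 0.22
    solver_tol: float = 1e-9
    max_grid: int | None = None

    def __post_init__(self) -> None:
        if not (self.kappa_mixture > 0 and self.kappa_components > 0):
            raise ValueError("denoising penalties kappa must be strictly positive")
        if self.max_grid is not None and self.max_grid < 2:
            raise ValueError("max_grid must be at least 2")


@dataclass(frozen=True)
class DeconvolutionResult:
    """Output of a deconvolution run.

    ``p`` are the raw signal proportions (``sum(p) + p0 == 1``), ``p0``
    the fraction of mixture signal labeled noise, ``p0_prime`` the
    fraction of library signal labeled missing, and ``proportions`` the
    reported composition ``p / sum(p)`` — the proportions renormalized
    over the explained signal.  ``objective`` is the optimal transport
    cost including both penalty terms, and ``plan`` the explicit optimal
    coupling (with vortex entries).
    """

    p: np.ndarray
    p0: float
    p0_prime: float
    proportions: np.ndarray
    objective: float
    plan: TransportPlan
    status: str
    config: DeconvolutionConfig | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        p.setflags(write=False)
        object.__setattr__(self, "p", p)
        prop = np.asarray(self.proportions, dtype=float)
        prop.setflags(write=False)
        object.__setattr__(self, "proportions", prop)


def _validate_result(res: DeconvolutionResult, atol: float = 1e-7) -> None:
    """Post-solve sanity checks; a violation indicates a solver failure."""
    p, p0, p0p = res.p, res.p0, res.p0_prime
    if (p < -atol).any() or p0 < -atol or p0p < -atol or p0 > 1 + atol or p0p > 1 + atol:
        raise SolverError(f"proportions out of range: p={p}, p0={p0}, p0'={p0p}")
    if abs(p.sum() + p0 - 1.0) > 1e-8:
        raise SolverError(f"mass balance violated: sum(p)+p0 = {p.sum() + p0}")
    if p.sum() > 0 and abs(res.proportions.sum() - 1.0) > 1e-8:
        raise SolverError("reported proportions do not sum to one")
    cfg = res.config
    km = cfg.kappa_mixture if cfg else 0.0
    kc = cfg.kappa_components if cfg else 0.0
    recomputed = res.plan.cost(km, kc)
    if abs(recomputed - res.objective) > max(atol, 1e-7):
        raise SolverError(
            f"plan cost {recomputed} disagrees with objective {res.objective}"
        )


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _union_grid(mixture: Spectrum, library: ComponentLibrary):
    grid = np.union1d(mixture.shifts, np.concatenate([c.shifts for c in library]))
    mix_mass = np.zeros(grid.size)
    mix_mass[np.searchsorted(grid, mixture.shifts)] = mixture.intensities
    comp_mass = np.zeros((library.k, grid.size))
    for i, c in enumerate(library):
        comp_mass[i, np.searchsorted(grid, c.shifts)] = c.intensities
    return grid, mix_mass, comp_mass


def _check_inputs(mixture: Spectrum, library: ComponentLibrary) -> None:
    if not mixture.normalized:
        raise SpectrumError("mixture spectrum must be normalized")
    for c in library:
        if not c.normalized:
            raise SpectrumError(f"library component {c.label!r} must be normalized")


def _apply_max_grid(mixture, library, max_grid):
    if max_grid is None:
        return mixture, library
    mixture = coarsen(mixture, max_grid)
    comps = tuple(coarsen(c, max_grid) for c in library)
    return mixture, ComponentLibrary(comps, library.names)


def _build_plan(
    grid: np.ndarray,
    mix_residual: np.ndarray,
    comp_residual: np.ndarray,
    removals_to_omega: np.ndarray,
    removals_from_xi: np.ndarray,
    kappa_mixture: float,
    kappa_components: float,
) -> TransportPlan:
    """Explicit coupling: monotone plan between the matched residual
    measures plus the vortex arcs."""
    keep_m = mix_residual > 1e-12
    keep_c = comp_residual > 1e-12
    wx = mix_residual[keep_m]
    wy = comp_residual[keep_c]
    # equalize totals (solver round-off) so the monotone merge terminates cleanly
    if wx.size and wy.size:
        sx, sy = wx.sum(), wy.sum()
        if sx > 0 and sy > 0 and abs(sx - sy) > 0:
            wy = wy * (sx / sy)
    entries: list[tuple[object, object, float]] = list(
        _monotone_entries(grid[keep_m], wx, grid[keep_c], wy)
    )
    for x, a in zip(grid, removals_to_omega):
        if a > 1e-12:
            entries.append((float(x), OMEGA, float(a)))
    for x, b in zip(grid, removals_from_xi):
        if b > 1e-12:
            entries.append((XI, float(x), float(b)))
    plan = TransportPlan(tuple(entries), 0.0)
    return TransportPlan(plan.entries, plan.cost(kappa_mixture, kappa_components))


def deconvolve(
    mixture: Spectrum,
    library: ComponentLibrary,
    config: DeconvolutionConfig | None = None,
) -> DeconvolutionResult:
    """Estimate mixture composition with both denoising vortices active.

    Solves, as a sparse LP on the merged support grid ``x_1 < .. < x_m``::

        minimize  flow_cost + kappa_mixture * p0 + kappa_components * p0'

    over proportions ``p_i >= 0``, per-node removals ``a_j`` (mixture mass
    at ``x_j`` sent to omega) and ``b_j`` (library mass at ``x_j`` supplied
    from xi), and signed inter-node flows on the grid segments, subject to
    flow conservation at every node, ``sum(p) + p0 = 1`` with
    ``p0 = sum(a)``, and the mixture scaled by ``1 - p0'`` with
    ``p0' = sum(b)``.  Direct omega-xi transport is disallowed, so the
    stated per-unit removal prices are exact.
    """
    config = config or DeconvolutionConfig()
    _check_inputs(mixture, library)
    mixture, library = _apply_max_grid(mixture, library, config.max_grid)
    grid, mix_mass, comp_mass = _union_grid(mixture, library)
    m = grid.size
    k = library.k
    gaps = np.diff(grid)
    nseg = m - 1

    # variable layout: [p (k) | t (1) | a (m) | b (m) | z+ (nseg) | z- (nseg)]
    off_t = k
    off_a = k + 1
    off_b = off_a + m
    off_zp = off_b + m
    off_zm = off_zp + nseg
    nvar = off_zm + nseg

    cost = np.zeros(nvar)
    cost[off_a:off_a + m] = config.kappa_mixture
    cost[off_b:off_b + m] = config.kappa_components
    cost[off_zp:off_zp + nseg] = gaps
    cost[off_zm:off_zm + nseg] = gaps

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def put(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # node balance at x_j:
    #   t*M_j - a_j + f_{j-1} - f_j - sum_i p_i N_ij + b_j = 0,   f_j = z+_j - z-_j
    for j in range(m):
        put(j, off_t, mix_mass[j])
        put(j, off_a + j, -1.0)
        put(j, off_b + j, 1.0)
        for i in range(k):
            if comp_mass[i, j] != 0.0:
                put(j, i, -comp_mass[i, j])
        if j > 0:
            put(j, off_zp + j - 1, 1.0)
            put(j, off_zm + j - 1, -1.0)
        if j < nseg:
            put(j, off_zp + j, -1.0)
            put(j, off_zm + j, 1.0)
    # sum(p) + sum(a) = 1
    r = m
    for i in range(k):
        put(r, i, 1.0)
    for j in range(m):
        put(r, off_a + j, 1.0)
    # t + sum(b) = 1
    r = m + 1
    put(r, off_t, 1.0)
    for j in range(m):
        put(r, off_b + j, 1.0)

    a_eq = coo_matrix((vals, (rows, cols)), shape=(m + 2, nvar)).tocsr()
    b_eq = np.zeros(m + 2)
    b_eq[m] = 1.0
    b_eq[m + 1] = 1.0

    # removal caps: a_j <= t*M_j ; b_j <= sum_i p_i N_ij
    ur, uc, uv = [], [], []
    nub = 0
    for j in range(m):
        ur.append(nub); uc.append(off_a + j); uv.append(1.0)
        ur.append(nub); uc.append(off_t); uv.append(-mix_mass[j])
        nub += 1
    for j in range(m):
        ur.append(nub); uc.append(off_b + j); uv.append(1.0)
        for i in range(k):
            if comp_mass[i, j] != 0.0:
                ur.append(nub); uc.append(i); uv.append(-comp_mass[i, j])
        nub += 1
    a_ub = coo_matrix((uv, (ur, uc)), shape=(nub, nvar)).tocsr()
    b_ub = np.zeros(nub)

    bounds = [(0.0, None)] * nvar
    bounds[off_t] = (0.0, 1.0)

    res = linprog(
        cost, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
        bounds=bounds, method="highs-ds",
        options={"primal_feasibility_tolerance": config.solver_tol,
                 "dual_feasibility_tolerance": config.solver_tol},
    )
    if res.status != 0:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")

    x = res.x
    p = np.clip(x[:k], 0.0, None)
    t = float(x[off_t])
    a = np.clip(x[off_a:off_a + m], 0.0, None)
    b = np.clip(x[off_b:off_b + m], 0.0, None)
    p0 = float(a.sum())
    p0_prime = float(b.sum())

    mix_residual = t * mix_mass - a
    comp_residual = comp_mass.T @ p - b
    plan = _build_plan(
        grid, np.clip(mix_residual, 0.0, None), np.clip(comp_residual, 0.0, None),
        a, b, config.kappa_mixture, config.kappa_components,
    )

    total_p = p.sum()
    proportions = p / total_p if total_p > 0 else np.full(k, np.nan)
    result = DeconvolutionResult(
        p=p, p0=p0, p0_prime=p0_prime, proportions=proportions,
        objective=float(res.fun), plan=plan,
        status=str(res.message) or "optimal", config=config,
    )
    _validate_result(result)
    return result


def deconvolve_unpenalized(
    mixture: Spectrum,
    library: ComponentLibrary,
    max_grid: int | None = None,
) -> DeconvolutionResult:
    """Plain Wasserstein regression: ``min_p W(mu, nu_p)`` with
    ``sum(p) = 1`` and no vortices.

    Equivalent to :func:`deconvolve` with both penalties set above the
    axis span, where removal is never worthwhile.
    """
    _check_inputs(mixture, library)
    mixture, library = _apply_max_grid(
        mixture, library, max_grid
    )
    grid, mix_mass, comp_mass = _union_grid(mixture, library)
    m = grid.size
    k = library.k
    gaps = np.diff(grid)
    nseg = m - 1

    off_zp = k
    off_zm = k + nseg
    nvar = k + 2 * nseg
    cost = np.zeros(nvar)
    cost[off_zp:off_zp + nseg] = gaps
    cost[off_zm:off_zm + nseg] = gaps

    rows, cols, vals = [], [], []
    for j in range(m):
        for i in range(k):
            if comp_mass[i, j] != 0.0:
                rows.append(j); cols.append(i); vals.append(comp_mass[i, j])
        # flow into node j from segment j-1, out on segment j
        if j > 0:
            rows.append(j); cols.append(off_zp + j - 1); vals.append(-1.0)
            rows.append(j); cols.append(off_zm + j - 1); vals.append(1.0)
        if j < nseg:
            rows.append(j); cols.append(off_zp + j); vals.append(1.0)
            rows.append(j); cols.append(off_zm + j); vals.append(-1.0)
    for i in range(k):
        rows.append(m); cols.append(i); vals.append(1.0)
    a_eq = coo_matrix((vals, (rows, cols)), shape=(m + 1, nvar)).tocsr()
    b_eq = np.concatenate([mix_mass, [1.0]])

    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0.0, None), method="highs-ds")
    if res.status != 0:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")
    p = np.clip(res.x[:k], 0.0, None)
    comp_total = comp_mass.T @ p
    plan = _build_plan(
        grid, mix_mass, np.clip(comp_total, 0.0, None),
        np.zeros(m), np.zeros(m), 0.0, 0.0,
    )
    result = DeconvolutionResult(
        p=p, p0=0.0, p0_prime=0.0, proportions=p / p.sum(),
        objective=float(res.fun), plan=plan,
        status=str(res.message) or "optimal", config=None,
    )
    _validate_result(result)
    return result


# ---------------------------------------------------------------------------
# Dense oracle
# ---------------------------------------------------------------------------

def deconvolve_oracle(
    mixture: Spectrum,
    library: ComponentLibrary,
    config: DeconvolutionConfig | None = None,
    max_support: int = 15,
    max_k: int = 3,
) -> tuple[float, np.ndarray]:
    """Independent dense formulation of the penalized estimator.

    One transport variable per (mixture point, library point) pair plus
    explicit vortex arcs — no segment flows, no shared code with
    :func:`deconvolve`.  Returns ``(objective, p)``.  Small instances
    only; used to verify the sparse formulation.
    """
    config = config or DeconvolutionConfig()
    _check_inputs(mixture, library)
    if library.k > max_k:
        raise SpectrumError(f"oracle supports at most {max_k} components")
    if mixture.n > max_support or any(c.n > max_support for c in library):
        raise SpectrumError(f"oracle supports at most {max_support} points per spectrum")

    xs = mixture.shifts
    mw = mixture.intensities
    ys = np.union1d(np.concatenate([c.shifts for c in library]), np.array([]))
    comp_mass = np.zeros((library.k, ys.size))
    for i, c in enumerate(library):
        comp_mass[i, np.searchsorted(ys, c.shifts)] = c.intensities
    n, q, k = xs.size, ys.size, library.k

    # variables: [gamma (n*q) | to_omega (n) | from_xi (q) | p (k) | t (1)]
    off_w = n * q
    off_x = off_w + n
    off_p = off_x + q
    off_t = off_p + k
    nvar = off_t + 1

    cost = np.zeros(nvar)
    cost[:off_w] = np.abs(xs[:, None] - ys[None, :]).ravel()
    cost[off_w:off_x] = config.kappa_mixture
    cost[off_x:off_p] = config.kappa_components

    a_eq = np.zeros((n + q + 2, nvar))
    b_eq = np.zeros(n + q + 2)
    for i in range(n):  # mixture marginal: sum_y gamma_iy + omega_i = t * mw_i
        a_eq[i, i * q:(i + 1) * q] = 1.0
        a_eq[i, off_w + i] = 1.0
        a_eq[i, off_t] = -mw[i]
    for j in range(q):  # library marginal: sum_x gamma_xj + xi_j = sum_c p_c N_cj
        a_eq[n + j, j:off_w:q] = 1.0
        a_eq[n + j, off_x + j] = 1.0
        a_eq[n + j, off_p:off_p + k] = -comp_mass[:, j]
    a_eq[n + q, off_p:off_p + k] = 1.0  # sum p + total omega mass = 1
    a_eq[n + q, off_w:off_x] = 1.0
    b_eq[n + q] = 1.0
    a_eq[n + q + 1, off_t] = 1.0  # t + total xi mass = 1
    a_eq[n + q + 1, off_x:off_p] = 1.0
    b_eq[n + q + 1] = 1.0

    bounds = [(0.0, None)] * nvar
    bounds[off_t] = (0.0, 1.0)
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError(f"oracle LP failed (status {res.status}): {res.message}")
    return float(res.fun), np.clip(res.x[off_p:off_p + k], 0.0, None)


# ---------------------------------------------------------------------------
# Error metrics and unit conversions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimationErrors:
    """``l1_error`` is unitless; ``avre`` and ``re`` are percentages."""

    l1_error: float
    avre: float
    re: np.ndarray


def estimation_errors(
    p_est: Sequence[float], p_true: Sequence[float]
) -> EstimationErrors:
    """Accuracy metrics for a composition estimate.

    ``l1_error`` is the sum of absolute proportion differences, ``re_i``
    the per-component relative error ``|p_est_i - p_true_i| / p_true_i``
    and ``avre`` their mean, both reported in percent.
    """
    est = np.asarray(p_est, dtype=float).ravel()
    true = np.asarray(p_true, dtype=float).ravel()
    if est.size != true.size:
        raise ValueError(f"length mismatch: {est.size} vs {true.size}")
    if (true <= 0).any():
        bad = np.nonzero(true <= 0)[0]
        raise ValueError(f"relative error undefined for p_true <= 0 at indices {bad.tolist()}")
    diff = np.abs(est - true)
    re = 100.0 * diff / true
    return EstimationErrors(l1_error=float(diff.sum()), avre=float(re.mean()), re=re)


def signal_to_molar(
    proportions: Sequence[float], proton_counts: Sequence[int]
) -> np.ndarray:
    """Convert signal proportions to molar proportions.

    A compound's signal is proportional to concentration times the number
    of contributing nuclei, so molar fractions are obtained by dividing
    each signal fraction by its proton count and renormalizing.
    """
    p = np.asarray(proportions, dtype=float).ravel()
    h = np.asarray(proton_counts, dtype=float).ravel()
    if p.size != h.size:
        raise ValueError(f"length mismatch: {p.size} vs {h.size}")
    if (h < 1).any():
        raise ValueError("proton counts must be positive integers")
    molar = p / h
    total = molar.sum()
    if total <= 0:
        raise ValueError("all proportions are zero")
    return molar / total


def absolute_concentrations(
    result: DeconvolutionResult,
    reference_index: int,
    reference_concentration: float,
    proton_counts: Sequence[int],
) -> np.ndarray:
    """Absolute concentrations from an external standard.

    When a reference spectrum of known concentration is algebraically
    added to the mixture and the same reference is present in the library,
    every concentration follows from the estimated proportions:
    ``c_i = c_ref * (p_i / H_i) / (p_ref / H_ref)``.
    """
    h = np.asarray(proton_counts, dtype=float).ravel()
    p = result.p
    if h.size != p.size:
        raise ValueError(f"expected {p.size} proton counts, got {h.size}")
    if (h < 1).any():
        raise ValueError("proton counts must be positive integers")
    if not 0 <= reference_index < p.size:
        raise IndexError(f"reference index {reference_index} out of range")
    p_ref = p[reference_index]
    if p_ref <= 0:
        raise ValueError("reference component not detected (p_ref = 0)")
    return reference_concentration * (p / h) / (p_ref / h[reference_index])


def parameter_sweep(
    mixture: Spectrum,
    library: ComponentLibrary,
    kappa_mixture_grid: Sequence[float],
    kappa_components_grid: Sequence[float],
    p_true: Sequence[float] | None = None,
    max_grid: int | None = None,
) -> pd.DataFrame:
    """Run the estimator over a grid of penalty values.

    Returns one row per ``(kappa_mixture, kappa_components)`` cell with
    ``p0``, ``p0_prime``, ``objective`` and — when the true composition is
    supplied — ``l1_error``, the sum of absolute differences between true
    and estimated proportions.
    """
    km_grid = list(kappa_mixture_grid)
    kc_grid = list(kappa_components_grid)
    if not km_grid or not kc_grid:
        raise ValueError("penalty grids must be non-empty")
    if any(v <= 0 for v in km_grid + kc_grid):
        raise ValueError("penalty grid values must be strictly positive")
    records = []
    for km in km_grid:
        for kc in kc_grid:
            cfg = DeconvolutionConfig(
                kappa_mixture=km, kappa_components=kc, max_grid=max_grid
            )
            res = deconvolve(mixture, library, cfg)
            rec = {
                "kappa_mixture": km,
                "kappa_components": kc,
                "p0": res.p0,
                "p0_prime": res.p0_prime,
                "objective": res.objective,
            }
            if p_true is not None:
                rec["l1_error"] = estimation_errors(res.proportions, p_true).l1_error
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def result_to_dict(
    result: DeconvolutionResult, names: Sequence[str] | None = None
) -> dict:
    cfg = result.config
    return {
        "names": list(names) if names is not None else None,
        "proportions": result.proportions.tolist(),
        "p": result.p.tolist(),
        "p0": result.p0,
        "p0_prime": result.p0_prime,
        "objective": result.objective,
        "kappa_mixture": cfg.kappa_mixture if cfg else None,
        "kappa_components": cfg.kappa_components if cfg else None,
        "status": result.status,
    }


def result_to_json(
    result: DeconvolutionResult,
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result, names), indent=2) + "\n")
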