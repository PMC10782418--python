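"""1-D optimal transport between spectra.

The Wasserstein-1 (earth mover's) distance between two normalized spectra
is the minimum total ``mass x ppm`` effort needed to reshape one into the
other.  In one dimension it has a closed form — the integral of the
absolute difference of the two cumulative distribution functions — which
this module evaluates in linear time on the merged support.  The optimal
coupling itself is the monotone (sorted-merge) plan, built here explicitly
so the flow of signal between spectra can be inspected and serialized.

A deliberately naive dense transportation LP (:func:`wasserstein_oracle`)
is included for verification on small instances; it shares no code with
the closed form.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .spectra import Spectrum, SpectrumError

__all__ = [
    "OMEGA",
    "XI",
    "TransportPlan",
    "wasserstein_distance",
    "transport_plan",
    "wasserstein_oracle",
    "plan_to_csv",
    "plan_from_csv",
]


class _Vortex:
    """Off-axis auxiliary point, equidistant (kappa) from every ppm position."""

    __slots__ = ("name",)

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:
        return self.name


#: Sink for excess mixture signal (mass removed from the mixture).
OMEGA = _Vortex("OMEGA")
#: Sink for excess library signal (mass missing from the mixture).
XI = _Vortex("XI")


def _require_normalized(*spectra: Spectrum) -> None:
    for s in spectra:
        if not s.normalized:
            raise SpectrumError(
                f"spectrum {s.label!r} must be normalized for transport computations"
            )


@dataclass(frozen=True)
class TransportPlan:
    """An explicit coupling between two discrete measures.

    ``entries`` holds ``(source, target, mass)`` triples where source and
    target are ppm positions, or the sentinels :data:`OMEGA` / :data:`XI`
    for mass routed to a denoising vortex.  ``total_cost`` is the plan's
    effort: ``sum(mass * distance)`` with vortex arcs priced at their
    kappa.
    """

    entries: tuple[tuple[object, object, float], ...]
    total_cost: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        for src, tgt, mass in self.entries:
            if mass < 0:
                raise ValueError(f"negative mass {mass} in plan entry ({src}, {tgt})")

    def source_marginal(self) -> dict[float, float]:
        """Aggregate mass leaving each on-axis source position."""
        out: dict[float, float] = {}
        for src, _tgt, mass in self.entries:
            if not isinstance(src, _Vortex):
                out[src] = out.get(src, 0.0) + mass
        return out

    def target_marginal(self) -> dict[float, float]:
        """Aggregate mass arriving at each on-axis target position."""
        out: dict[float, float] = {}
        for _src, tgt, mass in self.entries:
            if not isinstance(tgt, _Vortex):
                out[tgt] = out.get(tgt, 0.0) + mass
        return out

    def vortex_mass(self) -> tuple[float, float]:
        """Total mass sent to (omega, xi)."""
        to_omega = sum(m for _s, t, m in self.entries if t is OMEGA)
        from_xi = sum(m for s, _t, m in self.entries if s is XI)
        return to_omega, from_xi

    def cost(self, kappa_mixture: float = 0.0, kappa_components: float = 0.0) -> float:
        """Recompute the plan's effort from its entries."""
        total = 0.0
        for src, tgt, mass in self.entries:
            if tgt is OMEGA:
                total += mass * kappa_mixture
            elif src is XI:
                total += mass * kappa_components
            else:
                total += mass * abs(src - tgt)
        return total


# ---------------------------------------------------------------------------
# Closed form and monotone coupling
# ---------------------------------------------------------------------------

def _cdf_on(points: np.ndarray, masses: np.ndarray, grid: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(masses)])
    return cum[np.searchsorted(points, grid, side="right")]


def _w1(xs: np.ndarray, wx: np.ndarray, ys: np.ndarray, wy: np.ndarray) -> float:
    """W1 between two measures of equal total mass on sorted supports."""
    grid = np.union1d(xs, ys)
    if grid.size < 2:
        return 0.0
    fx = _cdf_on(xs, wx, grid[:-1])
    fy = _cdf_on(ys, wy, grid[:-1])
    return float(np.sum(np.abs(fx - fy) * np.diff(grid)))


def wasserstein_distance(mu: Spectrum, nu: Spectrum) -> float:
    """Wasserstein-1 distance between two normalized spectra, in ppm.

    Computed as the integral of ``|F_mu - F_nu|`` over the merged support
    grid.  Symmetric, non-negative, and zero exactly when the measures
    coincide.
    """
    _require_normalized(mu, nu)
    return _w1(mu.shifts, mu.intensities, nu.shifts, nu.intensities)


def _monotone_entries(
    xs: np.ndarray, wx: np.ndarray, ys: np.ndarray, wy: np.ndarray,
    atol: float = 1e-12,
) -> list[tuple[float, float, float]]:
    """Monotone (northwest-corner) coupling between equal-mass measures.

    In 1-D with cost |x - y| this coupling is optimal, because optimal
    plans never let transport paths cross.
    """
    entries: list[tuple[float, float, float]] = []
    i = j = 0
    remain_x = float(wx[0]) if len(wx) else 0.0
    remain_y = float(wy[0]) if len(wy) else 0.0
    while i < len(xs) and j < len(ys):
        move = min(remain_x, remain_y)
        if move > atol:
            entries.append((float(xs[i]), float(ys[j]), move))
        remain_x -= move
        remain_y -= move
        if remain_x <= atol:
            i += 1
            remain_x = float(wx[i]) if i < len(wx) else 0.0
        if remain_y <= atol:
            j += 1
            remain_y = float(wy[j]) if j < len(wy) else 0.0
    return entries


def transport_plan(mu: Spectrum, nu: Spectrum) -> TransportPlan:
    """Optimal coupling between two normalized spectra.

    The returned plan's marginals match the inputs and its cost equals
    :func:`wasserstein_distance` to within accumulation error.
    """
    _require_normalized(mu, nu)
    entries = _monotone_entries(mu.shifts, mu.intensities, nu.shifts, nu.intensities)
    cost = sum(m * abs(s - t) for s, t, m in entries)
    return TransportPlan(tuple(entries), cost)


# ---------------------------------------------------------------------------
# Dense LP oracle
# ---------------------------------------------------------------------------

def wasserstein_oracle(mu: Spectrum, nu: Spectrum, max_support: int = 30) -> float:
    """W1 via the full dense transportation linear program.

    Builds one variable per ``(x, y)`` support pair and solves the
    transportation polytope exactly.  Intentionally small-scale: it exists
    to verify the closed form and the deconvolution LP, not to be fast.
    """
    _require_normalized(mu, nu)
    n, m = mu.n, nu.n
    if n > max_support or m > max_support:
        raise SpectrumError(
            f"oracle supports at most {max_support} points per spectrum (got {n}, {m})"
        )
    cost = np.abs(mu.shifts[:, None] - nu.shifts[None, :]).ravel()
    rows, cols, vals = [], [], []
    for i in range(n):  # row sums = mu
        for j in range(m):
            rows.append(i)
            cols.append(i * m + j)
            vals.append(1.0)
    for j in range(m - 1):  # col sums = nu (last row redundant)
        for i in range(n):
            rows.append(n + j)
            cols.append(i * m + j)
            vals.append(1.0)
    a_eq = coo_matrix((vals, (rows, cols)), shape=(n + m - 1, n * m))
    b_eq = np.concatenate([mu.intensities, nu.intensities[: m - 1]])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if res.status != 0:  # pragma: no cover - transportation LP is always feasible
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(res.fun)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def plan_to_csv(plan: TransportPlan, path: str | Path) -> None:
    """Write a plan as CSV rows ``source,target,mass`` with vortex sentinels
    spelled ``OMEGA``/``XI``."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "mass"])
        for src, tgt, mass in plan.entries:
            writer.writerow([repr(src) if isinstance(src, _Vortex) else src,
                             repr(tgt) if isinstance(tgt, _Vortex) else tgt,
                             mass])


def plan_from_csv(
    path: str | Path,
    kappa_mixture: float = 0.0,
    kappa_components: float = 0.0,
) -> TransportPlan:
    """Read a plan written by :func:`plan_to_csv`; the cost is recomputed
    from the entries with the given vortex prices."""
    entries: list[tuple[object, object, float]] = []
    with Path(path).open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise SpectrumError(f"{path}: empty plan file")
        for row in reader:
            if not row:
                continue
            src: object = OMEGA if row[0] == "OMEGA" else XI if row[0] == "XI" else float(row[0])
            tgt: object = OMEGA if row[1] == "OMEGA" else XI if row[1] == "XI" else float(row[1])
            entries.append((src, tgt, float(row[2])))
    plan = TransportPlan(tuple(entries), 0.0)
    cost = plan.cost(kappa_mixture, kappa_components)
    return TransportPlan(plan.entries, cost)
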