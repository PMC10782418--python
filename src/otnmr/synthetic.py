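"""Synthetic spectrum and mixture generation.

This module produces component libraries and mixture spectra with the
geometric structure that makes real quantitative NMR hard: Lorentzian or
Gaussian multiplets, order-of-magnitude intensity imbalance between
components, contaminant resonances absent from the library, low-resolution
acquisition with heavy peak overlap, lineshape broadening from poor
shimming, and chemical shift drift between library and mixture (uniform
and position-dependent).  It is not a spin-system simulator — no
J-coupling evolution or roof effects — only the challenges the estimator
must survive are modeled.

Every operation is deterministic given its seed; there is no global
random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .spectra import ComponentLibrary, Spectrum, SpectrumError, coarsen, sum_spectra

__all__ = [
    "PeakSpec",
    "GridSpec",
    "Distortion",
    "MixtureScenario",
    "generate_component",
    "distort",
    "make_mixture",
    "preset_scenario",
    "PRESET_NAMES",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
]


@dataclass(frozen=True)
class PeakSpec:
    """One resonance: center (ppm), half-width at half-maximum (ppm),
    relative area, and lineshape."""

    center: float
    hwhm: float
    amplitude: float = 1.0
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise SpectrumError("peak width must be positive")
        if self.amplitude <= 0:
            raise SpectrumError("peak amplitude must be positive")
        if self.shape not in ("lorentzian", "gaussian"):
            raise SpectrumError(f"unknown lineshape {self.shape!r}")

    def profile(self, x: np.ndarray) -> np.ndarray:
        """Area-normalized lineshape times the relative area."""
        if self.shape == "lorentzian":
            return self.amplitude * (self.hwhm / math.pi) / (
                (x - self.center) ** 2 + self.hwhm ** 2
            )
        sigma = self.hwhm / math.sqrt(2.0 * math.log(2.0))
        return self.amplitude * np.exp(
            -0.5 * ((x - self.center) / sigma) ** 2
        ) / (sigma * math.sqrt(2.0 * math.pi))


@dataclass(frozen=True)
class GridSpec:
    """Uniform acquisition axis: ``n`` points spanning ``[lo, hi]`` ppm."""

    lo: float
    hi: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 16:
            raise SpectrumError("grid needs at least 16 points")
        if not self.hi > self.lo:
            raise SpectrumError("grid upper bound must exceed lower bound")

    def axis(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)


@dataclass(frozen=True)
class Distortion:
    """A single corruption operator applied to the mixture spectrum.

    kinds and parameters:

    - ``shift``: uniform translation; ``delta`` (ppm).
    - ``broaden``: convolution with a Lorentzian kernel of HWHM
      ``(factor - 1) * base_hwhm``; mass conserved.
    - ``downsample``: coarsen to ``n`` points.
    - ``contaminant``: mix in an extra normalized peak list with weight
      ``fraction``; ``peaks`` is a tuple of :class:`PeakSpec`.
    - ``noise``: add folded-normal perturbations of scale
      ``level * mean(intensity)`` per point, then renormalize.
    - ``warp``: position-dependent shift ``amplitude * sin(2*pi*(x - x0)/period)``,
      emulating per-peak drift.
    """

    kind: str
    delta: float = 0.0
    factor: float = 1.0
    base_hwhm: float = 0.01
    n: int = 0
    peaks: tuple[PeakSpec, ...] = ()
    fraction: float = 0.0
    level: float = 0.0
    amplitude: float = 0.0
    period: float = 1.0

    _KINDS = ("shift", "broaden", "downsample", "contaminant", "noise", "warp")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise SpectrumError(f"unknown distortion kind {self.kind!r}")
        if self.kind == "broaden" and self.factor < 1:
            raise SpectrumError("broadening factor must be >= 1")
        if self.kind == "downsample" and self.n < 16:
            raise SpectrumError("downsample target must be at least 16 points")
        if self.kind == "contaminant" and not (0 <= self.fraction < 1):
            raise SpectrumError("contaminant fraction must be in [0, 1)")
        if self.kind == "noise" and self.level < 0:
            raise SpectrumError("noise level must be non-negative")
        object.__setattr__(self, "peaks", tuple(self.peaks))


def generate_component(peaks: Sequence[PeakSpec], grid: GridSpec) -> Spectrum:
    """Evaluate a peak list on the grid and normalize.  Deterministic."""
    peaks = tuple(peaks)
    if not peaks:
        raise SpectrumError("peak list is empty")
    for pk in peaks:
        if not grid.lo <= pk.center <= grid.hi:
            raise SpectrumError(
                f"peak center {pk.center} ppm outside grid [{grid.lo}, {grid.hi}]"
            )
    x = grid.axis()
    y = np.zeros_like(x)
    for pk in peaks:
        y += pk.profile(x)
    y = np.clip(y, 0.0, None)
    return Spectrum(x, y / y.sum(), normalized=True)


def _broaden(s: Spectrum, factor: float, base_hwhm: float) -> Spectrum:
    if factor == 1.0:
        return s
    dx = np.diff(s.shifts)
    if dx.size == 0 or np.ptp(dx) > 1e-6 * dx.mean():
        raise SpectrumError("broadening requires a uniform axis")
    step = float(dx.mean())
    hwhm = (factor - 1.0) * base_hwhm
    half = max(int(math.ceil(12.0 * hwhm / step)), 1)
    offs = np.arange(-half, half + 1) * step
    kernel = (hwhm / math.pi) / (offs ** 2 + hwhm ** 2)
    kernel /= kernel.sum()
    y = np.convolve(s.intensities, kernel, mode="same")
    y = np.clip(y, 0.0, None)
    total = y.sum()
    if total <= 0:
        raise SpectrumError("broadening annihilated the spectrum")
    return Spectrum(s.shifts, y / total, label=s.label, normalized=True)


def distort(s: Spectrum, operator: Distortion, seed: int = 0) -> Spectrum:
    """Apply one corruption operator; the output is normalized."""
    if not s.normalized:
        s = s.normalize()
    op = operator
    if op.kind == "shift":
        return Spectrum(s.shifts + op.delta, s.intensities, label=s.label, normalized=True)
    if op.kind == "broaden":
        return _broaden(s, op.factor, op.base_hwhm)
    if op.kind == "downsample":
        out = coarsen(s, op.n)
        return out if out.normalized else out.normalize()
    if op.kind == "contaminant":
        if not op.peaks:
            raise SpectrumError("contaminant distortion needs a peak list")
        x = s.shifts
        y = np.zeros_like(x)
        for pk in op.peaks:
            y += pk.profile(x)
        if y.sum() <= 0:
            raise SpectrumError("contaminant peaks fall outside the spectrum axis")
        y /= y.sum()
        mixed = (1.0 - op.fraction) * s.intensities + op.fraction * y
        return Spectrum(x, mixed / mixed.sum(), label=s.label, normalized=True)
    if op.kind == "noise":
        rng = np.random.default_rng(seed)
        bumps = np.abs(rng.normal(0.0, op.level * s.intensities.mean(), size=s.n))
        y = s.intensities + bumps
        return Spectrum(s.shifts, y / y.sum(), label=s.label, normalized=True)
    if op.kind == "warp":
        x0 = float(s.shifts[0])
        shifts = s.shifts + op.amplitude * np.sin(
            2.0 * math.pi * (s.shifts - x0) / op.period
        )
        return Spectrum(shifts, s.intensities, label=s.label, normalized=True)
    raise SpectrumError(f"unknown distortion kind {op.kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class MixtureScenario:
    """A complete simulated experiment.

    Clean components are generated from ``component_peaklists`` on
    ``grid``; the mixture is their combination with ``proportions``,
    passed through ``distortions`` in order.  ``names`` label the
    components; ``seed`` drives any stochastic operator.
    """

    component_peaklists: tuple[tuple[PeakSpec, ...], ...]
    proportions: tuple[float, ...]
    grid: GridSpec
    distortions: tuple[Distortion, ...] = ()
    names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lists = tuple(tuple(pl) for pl in self.component_peaklists)
        props = tuple(float(p) for p in self.proportions)
        if len(lists) != len(props):
            raise SpectrumError("one proportion per component peak list required")
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise SpectrumError("proportions must be a probability vector")
        object.__setattr__(self, "component_peaklists", lists)
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "distortions", tuple(self.distortions))
        names = tuple(self.names) if self.names else tuple(
            f"component_{i + 1}" for i in range(len(lists))
        )
        if len(names) != len(lists):
            raise SpectrumError("names and component peak lists differ in length")
        object.__setattr__(self, "names", names)


def make_mixture(
    scenario: MixtureScenario,
) -> tuple[Spectrum, ComponentLibrary, np.ndarray, float]:
    """Realize a scenario.

    Returns ``(mixture, library, truth, contaminant_fraction)``: the
    library holds the clean components, the mixture is their true
    combination after all distortions, ``truth`` the component
    proportions, and ``contaminant_fraction`` the total weight of
    contaminant signal mixed in.  Byte-reproducible from the seed.
    """
    comps = tuple(
        generate_component(pl, scenario.grid).with_label(name).normalize()
        for pl, name in zip(scenario.component_peaklists, scenario.names)
    )
    library = ComponentLibrary(comps, scenario.names)
    mixture = sum_spectra(library, scenario.proportions)
    contaminant_fraction = 0.0
    for i, op in enumerate(scenario.distortions):
        mixture = distort(mixture, op, seed=scenario.seed + 7919 * (i + 1))
        if op.kind == "contaminant":
            contaminant_fraction = 1.0 - (1.0 - contaminant_fraction) * (1.0 - op.fraction)
    truth = np.asarray(scenario.proportions)
    return mixture, library, truth, contaminant_fraction


# ---------------------------------------------------------------------------
# Challenge presets
# ---------------------------------------------------------------------------

def _terpene_a(w: float) -> tuple[PeakSpec, ...]:
    """Pinene-like monoterpene: dense aliphatic envelope plus one olefinic peak."""
    return tuple(
        PeakSpec(c, w, a)
        for c, a in [(0.85, 3), (1.17, 1), (1.27, 1), (1.65, 3), (1.94, 1), (2.20, 2), (5.19, 1)]
    )


def _aromatic_ester(w: float) -> tuple[PeakSpec, ...]:
    """Benzyl-benzoate-like aromatic ester: CH2 singlet plus aromatic cluster."""
    return tuple(
        PeakSpec(c, w, a)
        for c, a in [(5.37, 2), (7.36, 2), (7.44, 2), (7.56, 1), (8.06, 2)]
    )


def _terpene_b(w: float) -> tuple[PeakSpec, ...]:
    """Limonene-like monoterpene: aliphatic peaks overlapping _terpene_a,
    plus exocyclic olefinics."""
    return tuple(
        PeakSpec(c, w, a)
        for c, a in [(1.48, 1), (1.66, 3), (1.72, 3), (1.98, 2), (2.08, 2), (4.70, 2), (5.40, 1)]
    )


def _fatty_ester(w: float) -> tuple[PeakSpec, ...]:
    """Isopropyl-myristate-like fatty ester: dominant methylene envelope."""
    return tuple(
        PeakSpec(c, w, a)
        for c, a in [(0.88, 3), (1.22, 10), (1.26, 10), (1.61, 2), (2.26, 2), (5.00, 1)]
    )


def _metabolites(w: float) -> list[tuple[PeakSpec, ...]]:
    """Five small-metabolite analogues.

    The upfield region is deliberately crowded — two CH3 doublet analogues
    0.15 ppm apart and two N-CH3 singlets only 0.02 ppm apart, as in real
    lactate/alanine and creatine/creatinine pairs — while each compound
    keeps one well-separated downfield signature (ladder spacing >= 0.3
    ppm).  The separated signatures are what keep the five components
    identifiable when the whole mixture drifts by up to ~0.1 ppm; a
    signature ladder packed tighter than twice the drift would make the
    pairs mathematically indistinguishable for any method.
    """
    tables = [
        [(1.33, 3), (4.55, 1)],
        [(1.48, 3), (3.75, 1)],
        [(3.03, 3), (4.10, 2)],
        [(3.05, 3), (4.85, 2)],
        [(3.20, 9), (3.52, 2), (5.25, 2)],
    ]
    return [tuple(PeakSpec(c, w, a) for c, a in t) for t in tables]


def _metabolites_spread(w: float) -> list[tuple[PeakSpec, ...]]:
    """Five small-metabolite analogues with every cross-component peak
    spacing >= 0.3 ppm.

    Used for the peak-drift scenario: when the whole mixture drifts by
    delta, components remain identifiable only if distinct compounds'
    resonances are separated by more than 2*delta — otherwise a drifted
    peak is genuinely closer to a neighbour's library position and no
    method can tell them apart.  This layout keeps the five components
    identifiable for drifts up to ~0.1 ppm.
    """
    tables = [
        [(1.30, 3), (4.55, 1)],
        [(1.60, 3), (3.75, 1)],
        [(2.05, 3), (4.10, 2)],
        [(2.50, 3), (4.85, 2)],
        [(3.20, 9), (2.90, 2), (5.25, 2)],
    ]
    return [tuple(PeakSpec(c, w, a) for c, a in t) for t in tables]


_METABOLITE_NAMES = (
    "metabolite_1", "metabolite_2", "metabolite_3", "metabolite_4", "metabolite_5"
)


def _preset_exp1(seed: int) -> MixtureScenario:
    # large intensity imbalance (~1:10) between two well-separated components
    w = 0.015
    return MixtureScenario(
        component_peaklists=(_terpene_a(w), _aromatic_ester(w)),
        proportions=(0.09, 0.91),
        grid=GridSpec(0.0, 9.0, 3500),
        distortions=(Distortion("noise", level=0.005),),
        names=("terpene_a", "aromatic_ester"),
        seed=seed,
    )


def _preset_exp2(seed: int) -> MixtureScenario:
    # overlapping aliphatic regions plus contaminant peaks far from the library
    w = 0.015
    contaminant = (PeakSpec(3.40, 0.02, 1), PeakSpec(6.60, 0.02, 1))
    return MixtureScenario(
        component_peaklists=(_terpene_b(w), _terpene_a(w)),
        proportions=(0.5, 0.5),
        grid=GridSpec(0.0, 9.0, 3500),
        distortions=(
            Distortion("contaminant", peaks=contaminant, fraction=0.03),
            Distortion("noise", level=0.005),
        ),
        names=("terpene_b", "terpene_a"),
        seed=seed,
    )


def _preset_exp3(seed: int) -> MixtureScenario:
    # benchtop acquisition: broad lines, nearly complete aliphatic overlap,
    # coarse digitization of the mixture
    w = 0.06
    return MixtureScenario(
        component_peaklists=(
            _aromatic_ester(w), _fatty_ester(w), _terpene_b(w), _terpene_a(w)
        ),
        proportions=(0.11, 0.73, 0.09, 0.07),
        grid=GridSpec(0.0, 10.0, 4096),
        distortions=(
            Distortion("downsample", n=1024),
            Distortion("noise", level=0.01),
        ),
        names=("aromatic_ester", "fatty_ester", "terpene_b", "terpene_a"),
        seed=seed,
    )


def _preset_exp4(seed: int) -> MixtureScenario:
    # well-shimmed library vs badly shimmed (broadened) mixture
    w = 0.012
    return MixtureScenario(
        component_peaklists=tuple(_metabolites(w)),
        proportions=(0.30, 0.22, 0.13, 0.20, 0.15),
        grid=GridSpec(0.5, 5.6, 3200),
        distortions=(
            Distortion("broaden", factor=4.0, base_hwhm=w),
            Distortion("noise", level=0.01),
        ),
        names=_METABOLITE_NAMES,
        seed=seed,
    )


def _preset_exp5(seed: int) -> MixtureScenario:
    # temperature-induced drift: uniform shift plus position-dependent warp
    w = 0.012
    return MixtureScenario(
        component_peaklists=tuple(_metabolites_spread(w)),
        proportions=(0.30, 0.22, 0.13, 0.20, 0.15),
        grid=GridSpec(0.5, 5.6, 3200),
        distortions=(
            Distortion("shift", delta=0.03),
            Distortion("warp", amplitude=0.005, period=2.5),
            Distortion("noise", level=0.01),
        ),
        names=_METABOLITE_NAMES,
        seed=seed,
    )


_PRESETS: dict[str, Callable[[int], MixtureScenario]] = {
    "exp1": _preset_exp1,
    "exp2": _preset_exp2,
    "exp3": _preset_exp3,
    "exp4": _preset_exp4,
    "exp5": _preset_exp5,
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def preset_scenario(name: str, seed: int = 0) -> MixtureScenario:
    """One of the five built-in challenge scenarios ``exp1`` .. ``exp5``:
    intensity imbalance, contamination, low resolution with overlap,
    lineshape distortion, and peak position mismatch."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise SpectrumError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return builder(seed)


# ---------------------------------------------------------------------------
# Declarative scenario files
# ---------------------------------------------------------------------------

def _peak_to_dict(pk: PeakSpec) -> dict:
    return {"center": pk.center, "hwhm": pk.hwhm, "amplitude": pk.amplitude, "shape": pk.shape}


def _peak_from_dict(d: dict) -> PeakSpec:
    return PeakSpec(**d)


def scenario_to_dict(sc: MixtureScenario) -> dict:
    return {
        "components": [
            {"name": name, "peaks": [_peak_to_dict(pk) for pk in pl]}
            for name, pl in zip(sc.names, sc.component_peaklists)
        ],
        "proportions": list(sc.proportions),
        "grid": {"lo": sc.grid.lo, "hi": sc.grid.hi, "n": sc.grid.n},
        "distortions": [
            {k: (list(v) if k == "peaks" else v)
             for k, v in (
                 ("kind", op.kind), ("delta", op.delta), ("factor", op.factor),
                 ("base_hwhm", op.base_hwhm), ("n", op.n),
                 ("peaks", [_peak_to_dict(pk) for pk in op.peaks]),
                 ("fraction", op.fraction), ("level", op.level),
                 ("amplitude", op.amplitude), ("period", op.period),
             )}
            for op in sc.distortions
        ],
        "seed": sc.seed,
    }


def scenario_from_dict(d: dict) -> MixtureScenario:
    comps = d["components"]
    distortions = []
    for od in d.get("distortions", []):
        od = dict(od)
        od["peaks"] = tuple(_peak_from_dict(p) for p in od.get("peaks", []))
        distortions.append(Distortion(**od))
    return MixtureScenario(
        component_peaklists=tuple(
            tuple(_peak_from_dict(p) for p in c["peaks"]) for c in comps
        ),
        proportions=tuple(d["proportions"]),
        grid=GridSpec(**d["grid"]),
        distortions=tuple(distortions),
        names=tuple(c.get("name", f"component_{i+1}") for i, c in enumerate(comps)),
        seed=int(d.get("seed", 0)),
    )


def load_scenario(path: str | Path) -> MixtureScenario:
    """Read a scenario from a JSON file (see :func:`scenario_to_dict`)."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SpectrumError(f"invalid scenario file {path}: {exc}") from exc
    return scenario_from_dict(d)
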