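"""Spectrum containers, file I/O, preprocessing and measure arithmetic.

A 1-D NMR spectrum is represented here as a discrete measure on the
chemical shift axis: a finite set of ``(shift, intensity)`` pairs.  After
normalization (intensities divided by their sum) the spectrum is a
discrete probability measure, which is the representation the optimal
transport machinery in :mod:`otnmr.transport` and :mod:`otnmr.deconv`
operates on.  Spectra do **not** need to share a common axis: the mixture
and every library component may each carry their own chemical shift grid,
with their own range and point count.

Chemical shift is always in ppm, which is field-independent and therefore
the natural unit for comparing spectra acquired on different instruments.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "ComponentLibrary",
    "SpectrumError",
    "ParseError",
    "EmptySpectrumError",
    "DegenerateSpectrumError",
    "read_spectrum",
    "write_spectrum",
    "preprocess",
    "sum_spectra",
    "coarsen",
]

NORM_ATOL = 1e-9


class SpectrumError(ValueError):
    """Base class for spectrum-related contract violations."""


class ParseError(SpectrumError):
    """A spectrum file could not be parsed; the message names the line."""


class EmptySpectrumError(SpectrumError):
    """A file or point list contained no data points."""


class DegenerateSpectrumError(SpectrumError):
    """Total intensity is zero, so no probability measure exists."""


@dataclass(frozen=True)
class Spectrum:
    """A discrete measure on the ppm axis.

    Parameters
    ----------
    shifts:
        Chemical shift positions in ppm.  Any order; duplicates are merged
        at construction by summing their intensities, and the result is
        stored in strictly increasing order.
    intensities:
        Signal intensity per position, arbitrary units.  Negative values
        are tolerated only while ``normalized`` is ``False`` (raw spectra
        carry baseline/phase artifacts); :func:`preprocess` clips them.
    label:
        Free-text name, e.g. the compound name.
    normalized:
        If ``True`` the intensities must be non-negative and sum to one
        within ``1e-9`` — i.e. the spectrum is a probability measure.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float).ravel()
        intens = np.asarray(self.intensities, dtype=float).ravel()
        if shifts.shape != intens.shape:
            raise SpectrumError(
                f"shifts and intensities differ in length: {shifts.size} vs {intens.size}"
            )
        if shifts.size == 0:
            raise EmptySpectrumError("a spectrum needs at least one point")
        if not (np.isfinite(shifts).all() and np.isfinite(intens).all()):
            raise SpectrumError("non-finite shift or intensity")
        order = np.argsort(shifts, kind="stable")
        shifts = shifts[order]
        intens = intens[order]
        # merge duplicate shift values: a measure is a set of (point, mass) pairs
        uniq, inverse = np.unique(shifts, return_inverse=True)
        if uniq.size != shifts.size:
            merged = np.zeros(uniq.size)
            np.add.at(merged, inverse, intens)
            shifts, intens = uniq, merged
        shifts.setflags(write=False)
        intens.setflags(write=False)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "intensities", intens)
        if self.normalized:
            if (intens < 0).any():
                raise SpectrumError("normalized spectrum has negative intensity")
            if abs(intens.sum() - 1.0) > NORM_ATOL:
                raise SpectrumError(
                    f"normalized spectrum sums to {intens.sum():.12g}, not 1"
                )

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.shifts.size)

    def __len__(self) -> int:
        return self.n

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.shifts.tolist(), self.intensities.tolist()))

    @property
    def total(self) -> float:
        """Total mass (sum of intensities)."""
        return float(self.intensities.sum())

    @property
    def span(self) -> float:
        """Width of the support in ppm."""
        return float(self.shifts[-1] - self.shifts[0])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = "normalized" if self.normalized else "raw"
        lab = f" {self.label!r}" if self.label else ""
        return f"<Spectrum{lab}: {self.n} points, {tag}>"

    # -- simple transforms -------------------------------------------------

    def normalize(self, label: str | None = None) -> "Spectrum":
        """Return the spectrum scaled to total mass one.

        Raises :class:`DegenerateSpectrumError` if the total mass is zero
        and :class:`SpectrumError` if any intensity is negative (clip with
        :func:`preprocess` first).
        """
        if (self.intensities < 0).any():
            raise SpectrumError(
                "cannot normalize a spectrum with negative intensities; "
                "use preprocess() to clip them first"
            )
        total = self.total
        if total <= 0:
            raise DegenerateSpectrumError("total intensity is zero")
        return Spectrum(
            self.shifts,
            self.intensities / total,
            label=label if label is not None else self.label,
            normalized=True,
        )

    def shifted(self, delta: float) -> "Spectrum":
        """Translate every point by ``delta`` ppm."""
        return replace(self, shifts=self.shifts + float(delta))

    def with_label(self, label: str) -> "Spectrum":
        return replace(self, label=label)

    def intensity_at(self, shift: float) -> float:
        """Point mass at ``shift`` (zero when ``shift`` is not a spectral point)."""
        i = np.searchsorted(self.shifts, shift)
        if i < self.n and self.shifts[i] == shift:
            return float(self.intensities[i])
        return 0.0


@dataclass(frozen=True)
class ComponentLibrary:
    """An ordered, named collection of normalized component spectra.

    The library plays the role of the basis in the mixture model: the
    mixture is approximated by a convex combination of its members.
    """

    components: tuple[Spectrum, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if len(comps) < 1:
            raise SpectrumError("a component library needs at least one spectrum")
        for c in comps:
            if not c.normalized:
                raise SpectrumError(
                    f"library component {c.label!r} is not normalized"
                )
        names = tuple(self.names) if self.names else tuple(
            c.label or f"component_{i + 1}" for i, c in enumerate(comps)
        )
        if len(names) != len(comps):
            raise SpectrumError("names and components differ in length")
        if len(set(names)) != len(names):
            raise SpectrumError(f"component names are not unique: {names}")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "names", names)

    @property
    def k(self) -> int:
        return len(self.components)

    def __len__(self) -> int:
        return self.k

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, i: int) -> Spectrum:
        return self.components[i]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SPLIT = re.compile(r"[,;\t ]+")


def _parse_two_column(lines: Iterable[str], source: str) -> Spectrum:
    shifts: list[float] = []
    intens: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = _SPLIT.split(line)
        if len(parts) < 2:
            raise ParseError(f"{source}: line {lineno}: expected two columns, got {line!r}")
        try:
            x = float(parts[0])
            y = float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{source}: line {lineno}: non-numeric value in {line!r}") from exc
        shifts.append(x)
        intens.append(y)
    if not shifts:
        raise EmptySpectrumError(f"{source}: no data points")
    return Spectrum(np.array(shifts), np.array(intens), label=Path(source).stem)


def _parse_jcamp(lines: Sequence[str], source: str) -> Spectrum:
    """Minimal JCAMP-DX reader: uncompressed XYPOINTS/PEAK TABLE ``(XY..XY)``
    and AFFN ``XYDATA=(X++(Y..Y))`` records only (no DIF/DUP/SQZ packing)."""
    fields: dict[str, str] = {}
    data_mode: str | None = None
    data_lines: list[str] = []
    for raw in lines:
        line = raw.strip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS", "PEAKTABLE"):
                data_mode = "xy" if key != "XYDATA" else "x++y"
                data_lines = []
            elif key == "END":
                break
            else:
                fields[key] = value
        elif data_mode is not None and line and not line.startswith("$$"):
            data_lines.append(line)
    if data_mode is None:
        raise ParseError(f"{source}: no XYDATA/XYPOINTS/PEAK TABLE record found")

    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    if data_mode == "xy":
        pairs: list[tuple[float, float]] = []
        for lineno, line in enumerate(data_lines, start=1):
            for chunk in line.split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                parts = _SPLIT.split(chunk)
                if len(parts) < 2:
                    raise ParseError(f"{source}: XY line {lineno}: bad pair {chunk!r}")
                try:
                    pairs.append((float(parts[0]) * xfac, float(parts[1]) * yfac))
                except ValueError as exc:
                    raise ParseError(
                        f"{source}: XY line {lineno}: non-numeric value in {chunk!r}"
                    ) from exc
        if not pairs:
            raise EmptySpectrumError(f"{source}: no data points")
        xs, ys = zip(*pairs)
        return Spectrum(np.array(xs), np.array(ys), label=fields.get("TITLE", Path(source).stem))

    # X++(Y..Y): each line starts with an X value followed by Y values
    xs_all: list[float] = []
    ys_all: list[float] = []
    npoints = int(float(fields["NPOINTS"])) if "NPOINTS" in fields else None
    firstx = float(fields["FIRSTX"]) if "FIRSTX" in fields else None
    lastx = float(fields["LASTX"]) if "LASTX" in fields else None
    if npoints is None or firstx is None or lastx is None:
        raise ParseError(f"{source}: XYDATA requires FIRSTX, LASTX and NPOINTS")
    dx = (lastx - firstx) / (npoints - 1) if npoints > 1 else 0.0
    idx = 0
    for lineno, line in enumerate(data_lines, start=1):
        parts = _SPLIT.split(line.strip())
        try:
            vals = [float(p) for p in parts if p]
        except ValueError as exc:
            raise ParseError(
                f"{source}: XYDATA line {lineno}: unsupported or non-numeric token in {line!r}"
            ) from exc
        for y in vals[1:]:
            xs_all.append((firstx + dx * idx) * xfac)
            ys_all.append(y * yfac)
            idx += 1
    if not xs_all:
        raise EmptySpectrumError(f"{source}: no data points")
    return Spectrum(np.array(xs_all), np.array(ys_all), label=fields.get("TITLE", Path(source).stem))


def read_spectrum(path: str | Path, format: str = "two_column") -> Spectrum:
    """Read a spectrum file.

    ``two_column`` is delimiter-separated ``(ppm, intensity)`` rows with
    ``#`` comments, in ascending or descending ppm order.  ``jcamp``
    accepts a small uncompressed subset of JCAMP-DX.  The result is
    un-normalized and sorted by ascending shift; duplicate shifts are
    merged by summing.
    """
    path = Path(path)
    if format not in ("two_column", "jcamp"):
        raise ValueError(f"unknown format {format!r}; expected 'two_column' or 'jcamp'")
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read spectrum file {path}: {exc}") from exc
    lines = text.splitlines()
    if format == "two_column":
        return _parse_two_column(lines, str(path))
    return _parse_jcamp(lines, str(path))


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    """Write a spectrum as two-column CSV (ppm, intensity)."""
    path = Path(path)
    with path.open("w") as fh:
        if spectrum.label:
            fh.write(f"# {spectrum.label}\n")
        for x, y in zip(spectrum.shifts, spectrum.intensities):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# Preprocessing and arithmetic
# ---------------------------------------------------------------------------

def preprocess(
    raw: Spectrum,
    trim_ranges: Sequence[tuple[float, float]] | None = None,
) -> Spectrum:
    """Turn a raw spectrum into a probability measure.

    Negative intensities (baseline/phase artifacts) are clipped to zero
    with a warning, points falling inside any of the closed ppm intervals
    in ``trim_ranges`` (e.g. solvent regions) are removed, and the result
    is normalized to total mass one.  Idempotent: preprocessing an already
    preprocessed spectrum (with the same trim ranges) is a no-op.
    """
    shifts = raw.shifts
    intens = raw.intensities
    if (intens < 0).any():
        clipped = float(-intens[intens < 0].sum())
        warnings.warn(
            f"clipped negative intensity (total magnitude {clipped:.4g}) "
            f"in spectrum {raw.label!r}",
            stacklevel=2,
        )
        intens = np.clip(intens, 0.0, None)
    if trim_ranges:
        keep = np.ones(shifts.size, dtype=bool)
        for lo, hi in trim_ranges:
            if hi < lo:
                lo, hi = hi, lo
            keep &= ~((shifts >= lo) & (shifts <= hi))
        if not keep.any():
            raise DegenerateSpectrumError(
                f"trim ranges removed every point of spectrum {raw.label!r}"
            )
        shifts = shifts[keep]
        intens = intens[keep]
    total = intens.sum()
    if total <= 0:
        raise DegenerateSpectrumError(
            f"spectrum {raw.label!r} has zero total intensity after clipping/trimming"
        )
    return Spectrum(shifts, intens / total, label=raw.label, normalized=True)


def sum_spectra(library: ComponentLibrary, proportions: Sequence[float]) -> Spectrum:
    """Mix library components with the given non-negative weights.

    The point masses are added on the union of the component supports:
    ``nu_p(s) = sum_j p_j * nu_j(s)``, with ``nu_j(s) = 0`` where ``s`` is
    not a spectral point of component ``j``.  If the weights form a
    probability vector the result is itself a probability measure.
    """
    p = np.asarray(proportions, dtype=float).ravel()
    if p.size != library.k:
        raise SpectrumError(f"expected {library.k} proportions, got {p.size}")
    if (p < 0).any():
        raise SpectrumError("proportions must be non-negative")
    shifts = np.concatenate([c.shifts for c in library])
    masses = np.concatenate([w * c.intensities for w, c in zip(p, library)])
    is_prob = abs(p.sum() - 1.0) <= NORM_ATOL
    return Spectrum(shifts, masses, label="mixture", normalized=is_prob)


def coarsen(s: Spectrum, max_points: int) -> Spectrum:
    """Reduce a spectrum to at most ``max_points`` support points.

    Points are grouped into ``max_points`` contiguous equal-width ppm bins;
    each non-empty bin collapses to a single point at the intensity-weighted
    mean shift carrying the bin's total mass.  Total mass is conserved, so
    the Wasserstein distance to the original is at most half the bin width.
    """
    if max_points < 2:
        raise SpectrumError("max_points must be at least 2")
    if s.n <= max_points:
        return s
    if (s.intensities < 0).any():
        raise SpectrumError("coarsen requires non-negative intensities")
    lo, hi = float(s.shifts[0]), float(s.shifts[-1])
    edges = np.linspace(lo, hi, max_points + 1)
    idx = np.clip(np.searchsorted(edges, s.shifts, side="right") - 1, 0, max_points - 1)
    mass = np.zeros(max_points)
    moment = np.zeros(max_points)
    np.add.at(mass, idx, s.intensities)
    np.add.at(moment, idx, s.intensities * s.shifts)
    occupied = mass > 0
    centers = moment[occupied] / mass[occupied]
    return Spectrum(centers, mass[occupied], label=s.label, normalized=s.normalized)
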