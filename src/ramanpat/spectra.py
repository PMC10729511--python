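"""Core data model for time-resolved vibrational spectra.

The central containers are :class:`Spectrum` (one trace), :class:`SpectraSet`
(a time series of traces on a shared wavenumber axis — the X-block of a
calibration), :class:`ReferenceTable` (offline analyte measurements per
sampling timepoint — the y-block) and :class:`RegionSet` (wavenumber windows
for truncation).

Conventions
-----------
* Wavenumber axes are stored strictly descending (the plotting convention of
  Raman/FTIR spectroscopy); readers flip ascending input.
* All times are decimal hours from inoculation.
* Region bounds are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, RangeError, ValidationError

__all__ = [
    "Spectrum",
    "SpectraSet",
    "ReferenceTable",
    "RegionSet",
    "resample_to_grid",
    "truncate_regions",
    "align_to_reference",
]


def _check_axis(wavenumbers: np.ndarray) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1:
        raise ValidationError("wavenumber axis must be 1-D")
    if w.size and np.isnan(w).any():
        raise ValidationError("wavenumber axis contains NaN")
    d = np.diff(w)
    if d.size and not (np.all(d > 0) or np.all(d < 0)):
        raise ValidationError("wavenumber axis must be strictly monotonic")
    return w


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum: wavenumbers (cm^-1, descending) and intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = _check_axis(self.wavenumbers)
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != w.shape:
            raise ValidationError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if y.size and np.isnan(y).any():
            raise ValidationError("intensities contain NaN")
        if w.size >= 2 and w[0] < w[-1]:  # ascending input -> flip
            w, y = w[::-1], y[::-1]
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class SpectraSet:
    """A stack of spectra sharing one axis, with acquisition times in hours.

    ``intensities`` has shape (n_spectra, n_channels); row i was acquired at
    ``times[i]``. ``labels`` carries free-form per-set metadata such as the
    modality tag (online-raman | hts-raman | hts-ftir) and preprocessing
    provenance.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    times: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = _check_axis(self.wavenumbers)
        y = np.asarray(self.intensities, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if y.ndim != 2:
            raise ValidationError("intensities must be a 2-D matrix")
        if y.shape[1] != w.size:
            raise ValidationError(
                f"channel mismatch: {y.shape[1]} columns vs {w.size} wavenumbers"
            )
        if t.ndim != 1 or t.size != y.shape[0]:
            raise ValidationError("one acquisition time required per spectrum row")
        if np.isnan(y).any() or np.isnan(t).any():
            raise ValidationError("intensities/times contain NaN")
        if t.size >= 2 and np.any(np.diff(t) < 0):
            raise ValidationError("acquisition times must be non-decreasing")
        if w.size >= 2 and w[0] < w[-1]:
            w, y = w[::-1], y[:, ::-1]
        self.wavenumbers = w
        self.intensities = np.ascontiguousarray(y)
        self.times = t

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        """Row ``i`` as a standalone :class:`Spectrum`."""
        return Spectrum(self.wavenumbers.copy(), self.intensities[i].copy())

    def with_intensities(self, intensities: np.ndarray, **label_updates) -> "SpectraSet":
        labels = {**self.labels, **label_updates}
        return SpectraSet(self.wavenumbers.copy(), intensities, self.times.copy(), labels)


@dataclass
class ReferenceTable:
    """Offline reference measurements: one row per sampling timepoint.

    ``values`` has shape (n_timepoints, n_analytes); NaN marks a missing
    measurement. Units are declared per analyte and drawn from the set used
    in fermentation reference analytics: g/L, mg/L, %w/w, ‰w/w.
    """

    timepoints: np.ndarray
    analytes: list[str]
    units: list[str]
    values: np.ndarray

    ALLOWED_UNITS = ("g/L", "mg/L", "%w/w", "‰w/w")

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if v.shape != (t.size, len(self.analytes)):
            raise ValidationError("values must be (n_timepoints, n_analytes)")
        if len(self.units) != len(self.analytes):
            raise ValidationError("one unit declaration required per analyte")
        for u in self.units:
            if u not in self.ALLOWED_UNITS:
                raise ValidationError(f"unknown unit {u!r}; expected one of {self.ALLOWED_UNITS}")
        finite = v[np.isfinite(v)]
        if finite.size and np.any(finite < 0):
            raise ValidationError("reference values must be >= 0 where present")
        self.timepoints = t
        self.values = v

    def column(self, analyte: str) -> np.ndarray:
        return self.values[:, self.analytes.index(analyte)]

    def unit_of(self, analyte: str) -> str:
        return self.units[self.analytes.index(analyte)]


@dataclass(frozen=True)
class RegionSet:
    """Non-overlapping closed wavenumber intervals, each given as (high, low)."""

    regions: tuple[tuple[float, float], ...]

    def __init__(self, regions) -> None:
        regs = tuple((float(h), float(l)) for h, l in regions)
        for h, l in regs:
            if h <= l:
                raise ValidationError(f"region ({h}, {l}): high bound must exceed low bound")
        ordered = sorted(regs, key=lambda r: -r[0])
        for (h1, l1), (h2, l2) in zip(ordered, ordered[1:]):
            if l1 <= h2:
                raise ValidationError(f"regions ({h1}, {l1}) and ({h2}, {l2}) overlap")
        object.__setattr__(self, "regions", regs)


def resample_to_grid(s: SpectraSet, grid) -> SpectraSet:
    """Linearly interpolate every spectrum onto a new wavenumber grid.

    The target grid must lie inside the source axis span; extrapolation is
    refused. Values at grid points shared with the source axis are preserved
    exactly.
    """
    grid = _check_axis(np.asarray(grid, dtype=float))
    lo, hi = s.wavenumbers.min(), s.wavenumbers.max()
    if grid.min() < lo or grid.max() > hi:
        raise RangeError(
            f"target grid [{grid.min()}, {grid.max()}] extends outside source axis [{lo}, {hi}]"
        )
    # np.interp needs ascending abscissae
    asc = s.wavenumbers[::-1]
    grid_desc = grid[::-1] if grid.size >= 2 and grid[0] < grid[-1] else grid
    out = np.empty((s.n_spectra, grid_desc.size))
    for i in range(s.n_spectra):
        out[i] = np.interp(grid_desc[::-1], asc, s.intensities[i, ::-1])[::-1]
    return SpectraSet(grid_desc, out, s.times.copy(), dict(s.labels))


def region_mask(wavenumbers: np.ndarray, r: RegionSet) -> np.ndarray:
    """Boolean mask of channels falling inside any region (inclusive bounds)."""
    w = np.asarray(wavenumbers, dtype=float)
    mask = np.zeros(w.shape, dtype=bool)
    for high, low in r.regions:
        mask |= (w >= low) & (w <= high)
    return mask


def truncate_regions(s: SpectraSet, r: RegionSet) -> SpectraSet:
    """Drop channels outside every region; keeps the descending channel order."""
    for high, low in r.regions:
        inside = (s.wavenumbers >= low) & (s.wavenumbers <= high)
        if not inside.any():
            raise ValidationError(f"region ({high}, {low}) contains no channels of the axis")
    mask = region_mask(s.wavenumbers, r)
    return SpectraSet(
        s.wavenumbers[mask], s.intensities[:, mask], s.times.copy(), dict(s.labels)
    )


def truncate_spectrum(s: Spectrum, r: RegionSet) -> Spectrum:
    for high, low in r.regions:
        inside = (s.wavenumbers >= low) & (s.wavenumbers <= high)
        if not inside.any():
            raise ValidationError(f"region ({high}, {low}) contains no channels of the axis")
    mask = region_mask(s.wavenumbers, r)
    return Spectrum(s.wavenumbers[mask], s.intensities[mask])


def align_to_reference(
    s: SpectraSet,
    ref: ReferenceTable,
    window_h: float = 0.5,
    policy: str = "mean",
):
    """Pair spectra with offline sampling timepoints.

    For each reference timepoint, ``policy='nearest'`` takes the single
    closest spectrum (ties broken toward the earlier one) and
    ``policy='mean'`` averages all spectra within ±``window_h`` hours.
    Returns ``(X, ref, matched_times)`` where X has one row per reference
    timepoint and ``matched_times`` lists the acquisition times that fed each
    row.

    Raises :class:`AlignmentError` listing every timepoint with no spectrum
    inside the window.
    """
    if policy not in ("nearest", "mean"):
        raise ValueError(f"unknown alignment policy {policy!r}")
    uncovered = [
        float(tp) for tp in ref.timepoints
        if not np.any(np.abs(s.times - tp) <= window_h)
    ]
    if uncovered:
        raise AlignmentError(f"no spectrum within ±{window_h} h of timepoints: {uncovered}")
    rows = []
    matched: list[list[float]] = []
    for tp in ref.timepoints:
        dist = np.abs(s.times - tp)
        if policy == "nearest":
            i = int(np.argmin(dist))  # argmin takes the first (earlier) on ties
            rows.append(s.intensities[i])
            matched.append([float(s.times[i])])
        else:
            sel = dist <= window_h
            rows.append(s.intensities[sel].mean(axis=0))
            matched.append([float(t) for t in s.times[sel]])
    X = np.vstack(rows)
    return X, ref, matched
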