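"""Spectral pretreatments for fermentation-broth Raman/FTIR series.

Four primitives — rubber-band (convex-hull) baseline subtraction,
Savitzky-Golay smoothing/derivation, anchor-peak normalization and extended
multiplicative signal correction (EMSC) — plus region truncation, composable
into ordered :class:`PreprocessRecipe` objects. Six named recipes cover the
standard online and at-line (HTS) processing chains:

``online_glass``
    rubber band → SG(9, 2, 0) → normalize to the 800 cm^-1 glass peak →
    truncate to 3050-2500 and 1800-650 cm^-1.
``online_water``
    as above but normalized to the 3200 cm^-1 water O-H band.
``online_emsc_d4`` / ``online_emsc_d6``
    rubber band → SG(9, 2, 0) → truncate → EMSC with polynomial terms up to
    degree 4 (or 6).
``hts_ftir``
    SG second derivative (15, 2, 2) → truncate to 3050-2800 and
    1800-900 cm^-1 → EMSC degree 2.
``hts_raman``
    SG(9, 2, 0) → truncate → rubber band → EMSC degree 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from numpy.polynomial import legendre
from scipy.signal import savgol_coeffs

from .errors import (
    DegenerateFitError,
    NormalizationError,
    ParameterError,
    RamanPatError,
    ValidationError,
)
from .spectra import RegionSet, SpectraSet, Spectrum, truncate_regions

__all__ = [
    "rubberband_baseline",
    "savitzky_golay",
    "peak_normalize",
    "emsc",
    "EMSCResult",
    "PreprocessRecipe",
    "apply_recipe",
    "builtin_recipe",
    "BUILTIN_RECIPES",
]


# --- rubber-band baseline -------------------------------------------------

def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew monotone-chain lower convex hull of points sorted by x."""
    stack: list[int] = []
    for i in range(x.size):
        while len(stack) >= 2:
            j, k = stack[-2], stack[-1]
            # pop k if it lies on or above the j->i chord
            if (x[k] - x[j]) * (y[i] - y[j]) - (x[i] - x[j]) * (y[k] - y[j]) <= 0:
                stack.pop()
            else:
                break
        stack.append(i)
    return np.asarray(stack, dtype=int)


def rubberband_baseline(s: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Subtract the rubber-band baseline (lower convex hull of the trace).

    The baseline is the lower convex hull of the (wavenumber, intensity)
    points, linearly interpolated between hull vertices; it touches the
    signal at the hull vertices (so the corrected first and last channels
    are exactly zero) and never exceeds the signal anywhere.

    Returns ``(corrected, baseline)``.
    """
    if len(s) < 3:
        raise ValidationError("rubber-band baseline needs at least 3 channels")
    # hull computed in ascending-x order
    x_asc = s.wavenumbers[::-1]
    y_asc = s.intensities[::-1]
    hull = _lower_hull_indices(x_asc, y_asc)
    base_asc = np.interp(x_asc, x_asc[hull], y_asc[hull])
    baseline = base_asc[::-1]
    corrected = s.intensities - baseline
    return (
        Spectrum(s.wavenumbers.copy(), corrected),
        Spectrum(s.wavenumbers.copy(), baseline),
    )


# --- Savitzky-Golay -------------------------------------------------------

def _grid_spacing(wavenumbers: np.ndarray) -> float:
    d = np.diff(wavenumbers)
    if d.size == 0:
        raise ParameterError("need at least 2 channels for a derivative scale")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("Savitzky-Golay requires a uniform wavenumber grid")
    return float(d[0])  # negative for the stored descending axis


def savitzky_golay(s: Spectrum, window: int, polyorder: int, deriv: int = 0) -> Spectrum:
    """Local least-squares polynomial smoothing / differentiation.

    Derivatives are reported per (cm^-1)^deriv with the sign convention of an
    increasing wavenumber axis. Edge channels are refit on the one-sided
    window truncated at the array bounds (no reflection padding), so the
    filter is well defined on truncated regions.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ParameterError(
            f"window must be odd and exceed polyorder (got window={window}, polyorder={polyorder})"
        )
    if deriv > polyorder:
        raise ParameterError("derivative order cannot exceed the polynomial order")
    n = len(s)
    if window > n:
        raise ParameterError(f"window {window} exceeds the {n} available channels")
    y = s.intensities
    h = window // 2
    out = np.empty(n)
    # interior: standard convolution with SG coefficients in index space
    coeffs = savgol_coeffs(window, polyorder, deriv=deriv, use="dot")
    for i in range(h, n - h):
        out[i] = coeffs @ y[i - h : i + h + 1]
    # edges: explicit truncated-window polynomial refit
    from math import factorial

    for i in list(range(0, min(h, n))) + list(range(max(n - h, h), n)):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        rel = np.arange(lo, hi) - i
        order = min(polyorder, rel.size - 1)
        if deriv > order:
            out[i] = 0.0
            continue
        V = np.vander(rel, order + 1, increasing=True)
        c, *_ = np.linalg.lstsq(V, y[lo:hi], rcond=None)
        out[i] = factorial(deriv) * c[deriv]
    if deriv > 0:
        out = out / _grid_spacing(s.wavenumbers) ** deriv
    return Spectrum(s.wavenumbers.copy(), out)


# --- anchor-peak normalization -------------------------------------------

def peak_normalize(s: Spectrum, anchor: float, halfwidth: float = 16.0) -> Spectrum:
    """Divide the spectrum by its maximum within ``anchor ± halfwidth`` cm^-1.

    The windowed maximum (rather than the single nearest channel) makes the
    anchor robust to grid offsets between instruments; the located peak maps
    to intensity 1. A non-positive window maximum signals a dead channel or
    a baseline that was not removed and raises :class:`NormalizationError`.
    """
    w = s.wavenumbers
    mask = (w >= anchor - halfwidth) & (w <= anchor + halfwidth)
    if not mask.any():
        raise ParameterError(
            f"normalization window {anchor}±{halfwidth} cm^-1 does not overlap the axis"
        )
    peak = float(s.intensities[mask].max())
    if peak <= 0:
        raise NormalizationError(
            f"window maximum {peak:g} at {anchor}±{halfwidth} cm^-1 is not positive"
        )
    return Spectrum(w.copy(), s.intensities / peak)


# --- EMSC ----------------------------------------------------------------

@dataclass
class EMSCResult:
    """EMSC decomposition: raw = b*reference + sum_i a_i P_i + residual.

    ``corrected`` holds (raw - sum a_i P_i)/b per spectrum; ``multiplicative``
    the scale factors b; ``additive`` the polynomial coefficients (one row per
    spectrum, columns orders 0..degree in the Legendre basis on the axis
    rescaled to [-1, 1]); ``reference`` the reference spectrum used.
    """

    corrected: SpectraSet
    multiplicative: np.ndarray
    additive: np.ndarray
    reference: Spectrum


def _legendre_basis(wavenumbers: np.ndarray, degree: int) -> np.ndarray:
    """(n_channels, degree+1) Legendre design on the axis rescaled to [-1, 1]."""
    lo, hi = wavenumbers.min(), wavenumbers.max()
    z = 2.0 * (wavenumbers - lo) / (hi - lo) - 1.0
    cols = []
    for d in range(degree + 1):
        c = np.zeros(d + 1)
        c[d] = 1.0
        cols.append(legendre.legval(z, c))
    return np.column_stack(cols)


def emsc(s: SpectraSet, reference="mean", degree: int = 4) -> EMSCResult:
    """Extended multiplicative signal correction.

    Each spectrum is regressed (ordinary least squares) onto the reference
    spectrum plus Legendre polynomials of order 0..degree; dividing out the
    reference scale b and subtracting the polynomial part removes
    multiplicative scatter and smooth additive baselines in one step.
    ``reference='mean'`` uses the channel-wise mean of ``s`` itself.
    """
    if degree < 0:
        raise ParameterError("EMSC degree must be >= 0")
    if s.n_channels < degree + 2:
        raise ParameterError(
            f"EMSC degree {degree} needs at least {degree + 2} channels, have {s.n_channels}"
        )
    if isinstance(reference, str):
        if reference != "mean":
            raise ParameterError(f"unknown EMSC reference {reference!r}")
        ref = Spectrum(s.wavenumbers.copy(), s.intensities.mean(axis=0))
    else:
        ref = reference
        if ref.wavenumbers.shape != s.wavenumbers.shape or not np.allclose(
            ref.wavenumbers, s.wavenumbers
        ):
            raise ValidationError("EMSC reference must share the data axis")
    P = _legendre_basis(s.wavenumbers, degree)
    design = np.column_stack([ref.intensities, P])  # (n_channels, degree+2)
    coefs, *_ = np.linalg.lstsq(design, s.intensities.T, rcond=None)
    b = coefs[0]
    a = coefs[1:].T  # (n_spectra, degree+1)
    bad = np.abs(b) < 1e-10
    if bad.any():
        raise DegenerateFitError(
            f"EMSC scale factor below tolerance for spectra at rows {np.nonzero(bad)[0].tolist()}"
        )
    corrected = (s.intensities - a @ P.T) / b[:, None]
    return EMSCResult(
        corrected=s.with_intensities(corrected),
        multiplicative=b,
        additive=a,
        reference=ref,
    )


# --- recipes --------------------------------------------------------------

_STEP_KINDS = {"rubberband", "savgol", "peak_normalize", "emsc", "truncate"}

_REQUIRED_PARAMS = {
    "rubberband": set(),
    "savgol": {"window", "polyorder", "deriv"},
    "peak_normalize": {"anchor", "halfwidth"},
    "emsc": {"degree"},
    "truncate": {"regions"},
}


@dataclass
class PreprocessRecipe:
    """An ordered, named list of preprocessing steps.

    Each step is ``(kind, params)`` with kind in rubberband | savgol |
    peak_normalize | emsc | truncate. Serializes deterministically to YAML.
    """

    name: str
    steps: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for kind, params in self.steps:
            if kind not in _STEP_KINDS:
                raise ParameterError(f"unknown step kind {kind!r}")
            missing = _REQUIRED_PARAMS[kind] - set(params)
            if missing:
                raise ParameterError(f"step {kind!r} missing parameters {sorted(missing)}")

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "steps": [{"kind": k, **{p: params[p] for p in sorted(params)}}
                      for k, params in self.steps],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessRecipe":
        doc = yaml.safe_load(text)
        steps = []
        for step in doc["steps"]:
            step = dict(step)
            kind = step.pop("kind")
            steps.append((kind, step))
        return cls(name=doc["name"], steps=steps)


def _apply_step(s: SpectraSet, kind: str, params: dict) -> SpectraSet:
    if kind == "truncate":
        return truncate_regions(s, RegionSet(params["regions"]))
    if kind == "emsc":
        return emsc(s, reference=params.get("reference", "mean"),
                    degree=params["degree"]).corrected
    # remaining kinds act per spectrum row
    out = np.empty_like(s.intensities)
    for i in range(s.n_spectra):
        row = Spectrum(s.wavenumbers, s.intensities[i])
        if kind == "rubberband":
            row = rubberband_baseline(row)[0]
        elif kind == "savgol":
            row = savitzky_golay(row, params["window"], params["polyorder"], params["deriv"])
        elif kind == "peak_normalize":
            row = peak_normalize(row, params["anchor"], params["halfwidth"])
        out[i] = row.intensities
    return s.with_intensities(out)


def apply_recipe(s: SpectraSet, r: PreprocessRecipe) -> SpectraSet:
    """Apply the recipe's steps strictly in listed order.

    Per-step provenance is appended to the output's ``labels['recipe']`` /
    ``labels['steps']`` metadata; step failures are re-raised annotated with
    the step index.
    """
    out = s
    applied = []
    for idx, (kind, params) in enumerate(r.steps):
        try:
            out = _apply_step(out, kind, params)
        except RamanPatError as exc:
            raise type(exc)(f"recipe {r.name!r} step {idx} ({kind}): {exc}") from exc
        applied.append({"kind": kind, **params})
    labels = {**out.labels, "recipe": r.name, "steps": applied}
    return SpectraSet(out.wavenumbers, out.intensities, out.times, labels)


_ONLINE_REGIONS = [(3050, 2500), (1800, 650)]
_FTIR_REGIONS = [(3050, 2800), (1800, 900)]

BUILTIN_RECIPES: dict[str, PreprocessRecipe] = {
    "online_glass": PreprocessRecipe(
        "online_glass",
        [
            ("rubberband", {}),
            ("savgol", {"window": 9, "polyorder": 2, "deriv": 0}),
            ("peak_normalize", {"anchor": 800, "halfwidth": 16}),
            ("truncate", {"regions": _ONLINE_REGIONS}),
        ],
    ),
    "online_water": PreprocessRecipe(
        "online_water",
        [
            ("rubberband", {}),
            ("savgol", {"window": 9, "polyorder": 2, "deriv": 0}),
            ("peak_normalize", {"anchor": 3200, "halfwidth": 16}),
            ("truncate", {"regions": _ONLINE_REGIONS}),
        ],
    ),
    "online_emsc_d4": PreprocessRecipe(
        "online_emsc_d4",
        [
            ("rubberband", {}),
            ("savgol", {"window": 9, "polyorder": 2, "deriv": 0}),
            ("truncate", {"regions": _ONLINE_REGIONS}),
            ("emsc", {"degree": 4}),
        ],
    ),
    "online_emsc_d6": PreprocessRecipe(
        "online_emsc_d6",
        [
            ("rubberband", {}),
            ("savgol", {"window": 9, "polyorder": 2, "deriv": 0}),
            ("truncate", {"regions": _ONLINE_REGIONS}),
            ("emsc", {"degree": 6}),
        ],
    ),
    "hts_ftir": PreprocessRecipe(
        "hts_ftir",
        [
            ("savgol", {"window": 15, "polyorder": 2, "deriv": 2}),
            ("truncate", {"regions": _FTIR_REGIONS}),
            ("emsc", {"degree": 2}),
        ],
    ),
    "hts_raman": PreprocessRecipe(
        "hts_raman",
        [
            ("savgol", {"window": 9, "polyorder": 2, "deriv": 0}),
            ("truncate", {"regions": _ONLINE_REGIONS}),
            ("rubberband", {}),
            ("emsc", {"degree": 2}),
        ],
    ),
}


def builtin_recipe(name: str) -> PreprocessRecipe:
    """Look up one of the shipped recipes by name."""
    try:
        return BUILTIN_RECIPES[name]
    except KeyError:
        raise ParameterError(
            f"unknown recipe {name!r}; available: {sorted(BUILTIN_RECIPES)}"
        ) from None
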