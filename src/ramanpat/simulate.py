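"""Synthetic fermentation spectra: kinetics, band library, instrument noise.

No raw spectra are deposited for the monitored fermentations, so this module
stands in for them: it simulates batch-fermentation kinetics for an
oleaginous yeast on glucose (``rhodotorula_glucose``) and a thraustochytrid
on glycerol (``schizochytrium_glycerol``), renders an online FT-Raman-like
time series as linear mixtures of component band spectra (substrate,
biomass protein, lipid, carotenoid, water, borosilicate-glass flow cell)
perturbed by multiplicative scatter, smooth additive drift and white noise,
and emits matched offline reference tables with measurement noise.

Model sketch
------------
* Biomass X(t): logistic growth from inoculum X0 toward capacity K at
  specific rate mu (1/h), clamped once the substrate is exhausted.
* Substrate S(t) = max(0, S0 − (X(t) − X0)/Yxs): yield-coupled consumption,
  so the conservation identity (X − X0)/Yxs + S − S0 = 0 holds exactly
  while S > 0.
* Lipid content (%w/w): logistic accumulation toward L_max.
* Carotenoid content (‰w/w): smooth peak at t_peak decaying to a terminal
  fraction, mirroring carotenoid turnover late in the batch.
* Spectra: raw(t) = m(t)·[Σ_c conc_c(t)·response_c·pure_c + water + glass]
  + drift_poly(t) + ε, with m(t) a per-spectrum log-normal scatter factor,
  drift a random low-order polynomial in the axis, and ε iid Gaussian.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, RangeError
from .spectra import ReferenceTable, SpectraSet, Spectrum

__all__ = [
    "BandSpec",
    "ComponentLibrary",
    "KineticsParams",
    "NoiseModel",
    "SyntheticRun",
    "simulate_kinetics",
    "pure_component_spectrum",
    "render_spectra",
    "make_reference_table",
    "generate_run",
    "default_library",
    "default_kinetics",
    "default_grid",
    "CONFIG_NAMES",
]


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: center and FWHM in cm^-1, relative height."""

    center: float
    fwhm: float
    height: float
    shape: str = "gaussian"  # gaussian | lorentzian

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ParameterError("band FWHM must be positive")
        if self.height < 0:
            raise ParameterError("band height must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ParameterError(f"unknown band shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        d = grid - self.center
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * math.log(2.0) * d**2 / self.fwhm**2)
        hw = self.fwhm / 2.0
        return self.height * hw**2 / (d**2 + hw**2)


@dataclass
class ComponentLibrary:
    """Named band sets plus per-component signal responses.

    ``response`` maps component → signal per unit concentration
    (intensity·L/g; the carotenoid entry is intensity·L/mg and carries a
    resonance-enhancement multiplier, configurable because 1064 nm
    excitation keeps the resonance comparatively weak).
    ``fixed_amplitude`` holds the concentration-independent contributions
    (water, glass flow cell).
    """

    components: dict[str, tuple[BandSpec, ...]]
    response: dict[str, float]
    fixed_amplitude: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, bands in self.components.items():
            if len(bands) < 2:
                raise ParameterError(f"component {name!r} needs >= 2 bands")
        for name, r in self.response.items():
            if r <= 0:
                raise ParameterError(f"response for {name!r} must be positive")


@dataclass
class KineticsParams:
    """Batch-fermentation parameters (units in field comments)."""

    X0: float            # inoculum biomass, g/L
    K: float             # biomass carrying capacity, g/L
    mu: float            # specific growth rate, 1/h
    S0: float            # starting substrate, g/L
    Yxs: float           # biomass yield on substrate, g/g
    lipid_min: float     # baseline lipid content, %w/w
    lipid_max: float     # plateau lipid content, %w/w
    lipid_t_mid: float   # logistic midpoint, h
    lipid_slope: float   # logistic steepness, 1/h
    caro_max: float      # peak carotenoid content, ‰w/w (= mg/g)
    caro_t_peak: float   # time of the content peak, h
    caro_width_rise: float    # Gaussian rise width, h
    caro_width_decay: float   # Gaussian decay width, h
    caro_terminal_frac: float  # content fraction retained at t -> inf

    def __post_init__(self):
        if self.mu < 0:
            raise ParameterError("growth rate mu must be >= 0")
        positives = (self.X0, self.K, self.S0, self.Yxs,
                     self.lipid_max, self.lipid_slope, self.caro_max,
                     self.caro_t_peak, self.caro_width_rise, self.caro_width_decay)
        if any(v <= 0 for v in positives):
            raise ParameterError("kinetic parameters must be positive")
        if self.X0 >= self.K:
            raise ParameterError("inoculum X0 must be below capacity K")
        if self.Yxs > 1:
            raise ParameterError("yield Yxs cannot exceed 1 g/g")


@dataclass
class NoiseModel:
    """Instrument-artifact model, fully reproducible from ``seed``.

    ``additive_sd`` is the white-noise sd in intensity units (None → 0.5% of
    the maximum clean signal); ``scatter_sd`` the sd of the log of the
    per-spectrum multiplicative factor; drift is a random polynomial of
    ``baseline_degree`` in the rescaled axis with coefficient sd
    ``baseline_sd`` (None → 1% of the maximum clean signal).
    """

    additive_sd: float | None = None
    scatter_sd: float = 0.1
    baseline_degree: int = 2
    baseline_sd: float | None = None
    seed: int = 0

    def __post_init__(self):
        for v in (self.additive_sd, self.scatter_sd, self.baseline_sd):
            if v is not None and v < 0:
                raise ParameterError("noise standard deviations must be >= 0")


# --- kinetics -------------------------------------------------------------

def simulate_kinetics(p: KineticsParams, t) -> dict:
    """Evaluate the kinetic model on a time grid (hours, starting at 0).

    Returns a dict of trajectories: t, X (g/L), S (g/L), lipid_content
    (%w/w), lipid_conc (g/L), carotenoid_content (‰w/w), carotenoid_conc
    (mg/L) and the flag ``substrate_exhausted``.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ParameterError("time grid must be increasing and start at 0")
    e = np.exp(p.mu * t)
    X = p.K * p.X0 * e / (p.K + p.X0 * (e - 1.0))
    # growth stops where the substrate runs out
    X_stop = p.X0 + p.S0 * p.Yxs
    exhausted = bool(np.any(X >= X_stop))
    X = np.minimum(X, X_stop)
    S = np.maximum(0.0, p.S0 - (X - p.X0) / p.Yxs)

    lipid = p.lipid_min + (p.lipid_max - p.lipid_min) / (
        1.0 + np.exp(-p.lipid_slope * (t - p.lipid_t_mid))
    )
    lipid = np.minimum(lipid, p.lipid_max)

    rise = np.exp(-((t - p.caro_t_peak) ** 2) / (2.0 * p.caro_width_rise**2))
    decay = p.caro_terminal_frac + (1.0 - p.caro_terminal_frac) * np.exp(
        -((t - p.caro_t_peak) ** 2) / (2.0 * p.caro_width_decay**2)
    )
    caro = p.caro_max * np.where(t <= p.caro_t_peak, rise, decay)

    return {
        "t": t,
        "X": X,
        "S": S,
        "lipid_content": lipid,                 # %w/w
        "lipid_conc": lipid / 100.0 * X,        # g/L
        "carotenoid_content": caro,             # ‰w/w = mg/g
        "carotenoid_conc": caro * X,            # mg/L
        "substrate_exhausted": exhausted,
    }


# --- band library ---------------------------------------------------------

def pure_component_spectrum(lib: ComponentLibrary, name: str, grid) -> Spectrum:
    """Sum of the component's band profiles on the given wavenumber grid."""
    grid = np.asarray(grid, dtype=float)
    try:
        bands = lib.components[name]
    except KeyError:
        raise LookupError(
            f"unknown component {name!r}; available: {sorted(lib.components)}"
        ) from None
    y = np.zeros_like(grid)
    for band in bands:
        y += band.profile(grid)
    return Spectrum(grid.copy(), y)


def default_library(substrate: str = "glucose") -> ComponentLibrary:
    """Band library built from the characteristic Raman assignments of
    fermentation broth: substrate C-H/C-OH bands, protein amide and
    phenylalanine bands, lipid C-H/C=O/C=C bands, resonance-enhanced
    carotenoid C=C/C-C bands, the broad water O-H envelope and the
    borosilicate flow-cell Si-O bands."""
    g = BandSpec
    substrate_bands = {
        "glucose": (
            g(2950, 60, 0.50), g(2896, 55, 0.60), g(1461, 25, 0.50),
            g(1345, 40, 0.45), g(1125, 35, 0.60), g(1060, 35, 0.55),
        ),
        "glycerol": (
            g(2954, 60, 0.60), g(2896, 55, 0.50), g(1467, 25, 0.50),
            g(1085, 45, 0.60), g(860, 22, 0.50),
        ),
    }[substrate]
    components = {
        "substrate": substrate_bands,
        "biomass": (
            g(2935, 70, 0.50), g(1658, 30, 0.50), g(1449, 25, 0.40),
            g(1608, 20, 0.20), g(1003, 12, 0.30, "lorentzian"),
        ),
        "lipid": (
            g(3010, 30, 0.20), g(2925, 50, 0.60), g(2855, 40, 0.80),
            g(1746, 25, 0.30), g(1655, 25, 0.40), g(1448, 25, 0.50),
            g(1303, 25, 0.35),
        ),
        "carotenoid": (
            g(1515, 25, 1.00, "lorentzian"), g(1152, 20, 0.70, "lorentzian"),
            g(1005, 15, 0.30, "lorentzian"),
        ),
        "water": (g(3250, 300, 1.00), g(3450, 250, 0.80), g(1645, 80, 0.25)),
        "glass": (g(1050, 150, 0.60), g(800, 40, 0.80)),
    }
    return ComponentLibrary(
        components=components,
        # intensity·L/g; carotenoid intensity·L/mg with a 50x resonance
        # enhancement already folded in (1e-3 = 0.02/1000 * 50/1... )
        response={
            "substrate": 0.020,
            "biomass": 0.030,
            "lipid": 0.040,
            "carotenoid": 1.0e-3,
        },
        fixed_amplitude={"water": 3.0, "glass": 1.5},
    )


def default_grid(spacing: float = 1.928, high: float = 3785.0, low: float = 650.0) -> np.ndarray:
    """Descending wavenumber axis, 3785→650 cm^-1 at the online digital
    resolution of 1.928 cm^-1 by default."""
    n = int(math.floor((high - low) / spacing)) + 1
    return high - spacing * np.arange(n)


# --- rendering ------------------------------------------------------------

def render_spectra(
    traj: dict,
    lib: ComponentLibrary,
    grid,
    cadence_min: float = 20.0,
    noise: NoiseModel | None = None,
) -> SpectraSet:
    """Render an online time series at a fixed acquisition cadence.

    One spectrum per cadence tick over [0, t_end] inclusive; trajectories
    are linearly interpolated to tick times. With noise off the rendered
    spectra are exact linear mixtures of the pure-component spectra plus the
    fixed water/glass contributions.
    """
    if cadence_min <= 0:
        raise ParameterError("cadence must be positive")
    noise = noise or NoiseModel(additive_sd=0.0, scatter_sd=0.0, baseline_sd=0.0)
    grid = np.asarray(grid, dtype=float)
    t_end = traj["t"][-1]
    n_ticks = int(math.floor(t_end * 60.0 / cadence_min)) + 1
    times = np.arange(n_ticks) * cadence_min / 60.0

    conc_keys = {"substrate": "S", "biomass": "X", "lipid": "lipid_conc",
                 "carotenoid": "carotenoid_conc"}
    pures = {name: pure_component_spectrum(lib, name, grid).intensities
             for name in lib.components}
    clean = np.zeros((n_ticks, grid.size))
    for name, key in conc_keys.items():
        conc = np.interp(times, traj["t"], traj[key])
        clean += np.outer(conc * lib.response[name], pures[name])
    for name, amp in lib.fixed_amplitude.items():
        clean += amp * pures[name][None, :]

    scale = float(np.abs(clean).max()) or 1.0
    add_sd = noise.additive_sd if noise.additive_sd is not None else 0.005 * scale
    base_sd = noise.baseline_sd if noise.baseline_sd is not None else 0.01 * scale

    rng = np.random.default_rng(noise.seed)
    m = np.exp(rng.normal(0.0, noise.scatter_sd, size=n_ticks)) if noise.scatter_sd else np.ones(n_ticks)
    out = clean * m[:, None]
    if base_sd:
        z = np.linspace(-1.0, 1.0, grid.size)
        V = np.vander(z, noise.baseline_degree + 1, increasing=True)
        coefs = rng.normal(0.0, base_sd, size=(n_ticks, noise.baseline_degree + 1))
        out = out + coefs @ V.T
    if add_sd:
        out = out + rng.normal(0.0, add_sd, size=out.shape)
    return SpectraSet(grid, out, times, {"modality": "online-raman", "synthetic": True})


def render_hts_spectra(
    traj: dict,
    lib: ComponentLibrary,
    grid,
    timepoints,
    noise: NoiseModel | None = None,
    modality: str = "hts-raman",
) -> SpectraSet:
    """At-line HTS spectra of withdrawn biomass: content-weighted mixtures of
    biomass, lipid and carotenoid components (no broth, water or glass)."""
    noise = noise or NoiseModel(additive_sd=0.0, scatter_sd=0.0, baseline_sd=0.0)
    grid = np.asarray(grid, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    lipid = np.interp(timepoints, traj["t"], traj["lipid_content"]) / 100.0   # g/g
    caro = np.interp(timepoints, traj["t"], traj["carotenoid_content"])       # mg/g
    protein = np.clip(1.0 - lipid, 0.0, None)
    pures = {n: pure_component_spectrum(lib, n, grid).intensities
             for n in ("biomass", "lipid", "carotenoid")}
    clean = (
        np.outer(protein, pures["biomass"])
        + np.outer(lipid, pures["lipid"])
        + np.outer(caro * 0.02, pures["carotenoid"])
    )
    scale = float(np.abs(clean).max()) or 1.0
    add_sd = noise.additive_sd if noise.additive_sd is not None else 0.005 * scale
    rng = np.random.default_rng(noise.seed)
    m = np.exp(rng.normal(0.0, noise.scatter_sd, size=timepoints.size)) if noise.scatter_sd else 1.0
    out = clean * np.atleast_1d(m)[:, None] + rng.normal(0.0, add_sd, size=clean.shape)
    return SpectraSet(grid, out, timepoints, {"modality": modality, "synthetic": True})


# --- reference tables -----------------------------------------------------

DEFAULT_CV_PCT = {
    "substrate": 2.0,
    "Cell dry weight": 3.0,
    "Total lipids": 5.0,
    "Total carotenoids": 5.0,
}


def make_reference_table(
    traj: dict,
    timepoints,
    cv_pct: dict | None = None,
    seed: int = 0,
    substrate_name: str = "Glucose",
) -> ReferenceTable:
    """Offline reference values at the sampling timepoints.

    True trajectory values are perturbed by multiplicative Gaussian noise of
    the stated coefficient of variation (percent, per analyte); negative
    draws are clamped to 0. Analytes and units follow offline fermentation
    analytics: substrate and cell dry weight in g/L, total lipids in g/L,
    total carotenoids in mg/L.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.min() < traj["t"][0] or timepoints.max() > traj["t"][-1]:
        raise RangeError("sampling timepoints outside the simulated span")
    cv = {**DEFAULT_CV_PCT, **(cv_pct or {})}
    truth = {
        substrate_name: np.interp(timepoints, traj["t"], traj["S"]),
        "Cell dry weight": np.interp(timepoints, traj["t"], traj["X"]),
        "Total lipids": np.interp(timepoints, traj["t"], traj["lipid_conc"]),
        "Total carotenoids": np.interp(timepoints, traj["t"], traj["carotenoid_conc"]),
    }
    units = {substrate_name: "g/L", "Cell dry weight": "g/L",
             "Total lipids": "g/L", "Total carotenoids": "mg/L"}
    rng = np.random.default_rng(seed)
    cols = []
    for name, vals in truth.items():
        c = cv.get(name, cv.get("substrate", 0.0)) / 100.0
        noisy = vals * (1.0 + rng.normal(0.0, c, size=vals.size)) if c else vals.copy()
        cols.append(np.clip(noisy, 0.0, None))
    analytes = list(truth)
    return ReferenceTable(
        timepoints=timepoints,
        analytes=analytes,
        units=[units[a] for a in analytes],
        values=np.column_stack(cols),
    )


# --- run configurations ---------------------------------------------------

def default_kinetics(config_name: str) -> KineticsParams:
    """Kinetic defaults reproducing the printed batch anchors: glucose
    52.2 g/L fully consumed with ~18.3 g/L final CDW; glycerol 55 g/L with
    ~77% consumed and ~26.4 g/L final CDW; lipid plateau ~66%w/w (yeast) /
    ~43%w/w (thraustochytrid); carotenoid content peaking at 48 h / 30 h."""
    if config_name == "rhodotorula_glucose":
        return KineticsParams(
            X0=0.32, K=18.35, mu=0.10, S0=52.2, Yxs=(18.35 - 0.32) / 52.2,
            lipid_min=4.0, lipid_max=66.5, lipid_t_mid=45.0, lipid_slope=0.09,
            caro_max=12.25, caro_t_peak=48.0, caro_width_rise=16.0,
            caro_width_decay=30.0, caro_terminal_frac=8.98 / 12.25,
        )
    if config_name == "schizochytrium_glycerol":
        return KineticsParams(
            X0=1.5, K=26.5, mu=0.09, S0=55.0, Yxs=(26.5 - 1.5) / (0.77 * 55.0),
            lipid_min=8.0, lipid_max=43.0, lipid_t_mid=20.0, lipid_slope=0.12,
            caro_max=0.40, caro_t_peak=30.0, caro_width_rise=12.0,
            caro_width_decay=45.0, caro_terminal_frac=0.33 / 0.40,
        )
    raise LookupError(
        f"unknown config {config_name!r}; valid: {sorted(CONFIG_NAMES)}"
    )


_CONFIG_META = {
    "rhodotorula_glucose": {
        "substrate": "Glucose",
        "library_substrate": "glucose",
        "timepoints": [4, 8, 12, 16, 20, 24, 32, 40, 48, 72, 96, 120],
        "grid_spacing": 1.928,
    },
    "schizochytrium_glycerol": {
        "substrate": "Glycerol",
        "library_substrate": "glycerol",
        "timepoints": [8, 16, 24, 30, 36, 42, 48, 60, 72, 84, 96, 120],
        "grid_spacing": 3.856,
    },
}

CONFIG_NAMES = tuple(_CONFIG_META)


@dataclass
class SyntheticRun:
    """Everything one simulated fermentation produces."""

    config_name: str
    replicate: str
    seed: int
    kinetics: KineticsParams
    online: SpectraSet
    hts_raman: SpectraSet
    hts_ftir: SpectraSet
    reference: ReferenceTable
    truth: dict  # the exact trajectories used
    substrate_name: str


def generate_run(
    config_name: str,
    seed: int = 0,
    replicate: str = "control",
    t_end: float = 120.0,
    cadence_min: float = 20.0,
    noise: NoiseModel | None = None,
) -> SyntheticRun:
    """Simulate one bioreactor run and render all spectral modalities.

    ``replicate`` is 'control' or 'loop', emulating the duplicate-reactor
    design (with and without the recirculatory flow-cell loop): the loop
    replicate shares the kinetic parameters with seeded perturbations of at
    most ±2% on mu, S0 and K, so paired trajectories stay within a few
    percent of each other and can serve as independent test sets.
    """
    if config_name not in _CONFIG_META:
        raise LookupError(f"unknown config {config_name!r}; valid: {sorted(CONFIG_NAMES)}")
    if replicate not in ("control", "loop"):
        raise ParameterError("replicate must be 'control' or 'loop'")
    meta = _CONFIG_META[config_name]
    params = default_kinetics(config_name)
    ss = np.random.SeedSequence([seed, CONFIG_NAMES.index(config_name)])
    s_perturb, s_online, s_ref, s_raman, s_ftir = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    if replicate == "loop":
        rng = np.random.default_rng(s_perturb)
        d = rng.uniform(-0.02, 0.02, size=3)
        params = replace(
            params,
            mu=params.mu * (1 + d[0]),
            S0=params.S0 * (1 + d[1]),
            K=params.K * (1 + d[2]),
        )
        params = replace(params, Yxs=min(params.Yxs, 1.0))
        s_online += 1
        s_ref += 1
        s_raman += 1
        s_ftir += 1

    t = np.linspace(0.0, t_end, int(t_end * 3) + 1)  # 20-min resolution grid
    traj = simulate_kinetics(params, t)
    lib = default_library(meta["library_substrate"])
    grid = default_grid(spacing=meta["grid_spacing"])
    base_noise = noise or NoiseModel()
    online = render_spectra(
        traj, lib, grid, cadence_min=cadence_min,
        noise=replace(base_noise, seed=s_online),
    )
    tp = [x for x in meta["timepoints"] if x <= t_end]
    reference = make_reference_table(
        traj, tp, seed=s_ref, substrate_name=meta["substrate"]
    )
    hts_raman = render_hts_spectra(
        traj, lib, grid, tp, noise=replace(base_noise, seed=s_raman), modality="hts-raman"
    )
    hts_ftir = render_hts_spectra(
        traj, lib, grid, tp, noise=replace(base_noise, seed=s_ftir), modality="hts-ftir"
    )
    return SyntheticRun(
        config_name=config_name,
        replicate=replicate,
        seed=seed,
        kinetics=params,
        online=online,
        hts_raman=hts_raman,
        hts_ftir=hts_ftir,
        reference=reference,
        truth=traj,
        substrate_name=meta["substrate"],
    )
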