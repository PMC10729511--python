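# Methods

## Data model and conventions

Spectra live on a strictly monotonic wavenumber axis stored **descending**
(the plotting convention of vibrational spectroscopy); ascending input is
flipped on ingestion, consistently with the intensity rows. All acquisition
and sampling times are decimal hours from inoculation. Truncation regions
are closed intervals, inclusive on both bounds. The canonical on-disk
format is a wide CSV (first column `wavenumber_cm-1`, remaining headers the
acquisition times); JCAMP-DX (single block, AFFN-encoded XYDATA/XYPOINTS)
is supported read-only as an exchange format for single spectra. Reference
tables are long-form CSV (`time_h, analyte, units, value`) with units drawn
from {g/L, mg/L, %w/w, ‰w/w}; a missing value drops that timepoint for
that analyte only.

## Preprocessing

**Rubber-band baseline.** The baseline is the lower convex hull of the
(wavenumber, intensity) point set, computed by Andrew's monotone chain and
linearly interpolated between hull vertices. This is the canonical
definition of the correction; it is idempotent (the hull of a corrected
spectrum is the zero line), never exceeds the signal, and pins both
endpoints of the corrected spectrum to zero. Vendor implementations add an
iterative support-point refinement whose details are undocumented; the
plain hull is used deliberately.

**Savitzky–Golay.** Local least-squares polynomial filtering in index
space. Derivatives are rescaled by (grid spacing)^deriv so they are per
(cm⁻¹)^deriv, with the sign convention of an increasing wavenumber axis.
Edge channels are refit on the window truncated at the array bounds rather
than reflected, so no out-of-range channels are fabricated on truncated
regions. A uniform grid is required for derivatives.

**Anchor-peak normalization.** Division by the maximum intensity inside
anchor ± halfwidth. The default halfwidth of 16 cm⁻¹ (about two resolution
elements at 8 cm⁻¹ spectral resolution) makes the anchor robust to grid
offsets between instruments running at different digital resolutions
(1.928 vs 3.856 cm⁻¹). Peak height, not band integral, is used for the
3200 cm⁻¹ water anchor; a non-positive window maximum raises an error
because it indicates the baseline was not removed first.

**EMSC.** Per spectrum, ordinary least squares onto
[reference, P₀…P_d] where Pᵢ are Legendre polynomials on the axis rescaled
to [−1, 1] (orthogonal basis for conditioning; coefficients are reported in
that basis). "Degree d" always includes all orders 0..d, so the constant
term is present. The default reference is the channel-wise mean of the set
being corrected. A scale factor |b| < 1e−10 is a degenerate fit and raises.

**Recipes.** Step order is significant and preserved exactly; the six
shipped recipes encode the standard chains (glass/water normalization
recipes normalize then truncate; the EMSC recipes truncate before EMSC; the
HTS-FTIR recipe runs on second derivatives; the HTS-Raman recipe smooths,
truncates, baselines, then applies EMSC). Recipes serialize
deterministically to YAML, and applying a recipe twice to identical input
gives bit-identical output.

## Calibration

PLS1 by NIPALS on mean-centered X and y, no variance scaling — y stays in
native units so RMSE is directly interpretable, and spectra after a recipe
are already on a common scale. Prediction uses the collapsed regression
vector B = W(PᵀW)⁻¹q, which matches sequential score-deflation prediction
to numerical precision. Leave-one-out cross-validation refits every fold
from scratch, re-centering inside the fold (the statistically correct
choice); A_opt = argmin RMSE_CV with ties to fewer components; the default
ceiling is A_max = min(10, n−2). R² is the prediction form 1 − SSE/SST,
which admits negative CV values. Relative RMSE is 100·RMSE/max(reference
values); rendered percentages round half-up to one decimal — rounding is
display-only, full precision is kept in machine-readable output. PCA is
mean-centered SVD with each loading's largest-magnitude element made
positive; Pearson correlation matrices use pairwise-complete observations
(minimum 3 pairs) and flag zero-variance series as NaN rather than 0.

Spectra are paired to offline timepoints by averaging all spectra within
±0.5 h (default) or taking the nearest spectrum (ties to the earlier one).
Averaging is the default because a single acquisition takes ~15 min and is
correspondingly noisy; both policies are exposed because no single pairing
rule is canonical.

## Synthetic data generator

The generator emulates a 120-h batch fermentation observed online every
20 min (361 spectra including t = 0) with 12 offline sampling timepoints.
Kinetic forms are the package's own choice of the simplest shapes matching
batch-fermentation phenomenology:

* biomass X(t): logistic (X0, K, mu), clamped at X0 + S0·Yxs once the
  substrate is exhausted;
* substrate S(t) = max(0, S0 − (X − X0)/Yxs), so yield conservation holds
  exactly on every grid point while S > 0;
* lipid content: logistic between lipid_min and lipid_max (%w/w);
* carotenoid content: Gaussian rise to a peak at t_peak, Gaussian decay to
  a terminal fraction (‰w/w), reflecting pigment turnover late in the run.

Defaults for the two configurations were derived analytically, once, from
the published batch anchors (glucose 52.2 g/L fully consumed, final CDW
18.3 g/L; glycerol 55 g/L with 77% consumed, final CDW 26.4 g/L; lipid
plateau 66.5/43 %w/w; carotenoid peak 12.25 ‰w/w at 48 h decaying to
8.98 ‰w/w): e.g. for the glucose run X0 = 0.32 (the smallest observed CDW),
K = 18.35, Yxs = (K − X0)/S0 ≈ 0.345 g/g, and mu = 0.10 h⁻¹ so the culture
saturates shortly before 120 h.

Spectra are linear mixtures: each component (substrate, biomass protein,
lipid, carotenoid) contributes its band set (Gaussian/Lorentzian profiles
at literature band positions, FWHM 12–70 cm⁻¹ in the fingerprint and
200–300 cm⁻¹ for the water O–H envelope) scaled by concentration × response,
plus fixed water and glass contributions. Responses are invented
(unknowable from published data): 0.02–0.04 intensity·L/g, and
10⁻³ intensity·L/mg for carotenoids, i.e. a 50× resonance-enhancement
factor that keeps pigments visible without masking other analytes.
Instrument artifacts are a per-spectrum log-normal scatter factor
(sd 0.1 on the log), a random degree-2 polynomial drift (coefficient sd 1%
of the maximum clean signal) and iid Gaussian noise (sd 0.5% of the maximum
clean signal). Everything is reproducible from one integer seed; replicate
("loop") runs perturb mu, S0 and K by at most ±2% to mimic
duplicate-reactor variability for cross-replicate validation.

What the generator does **not** emulate: nonlinear detector response,
fluorescence photobleaching dynamics, cosmic-ray spikes, temperature- or
pH-dependent band shifts, fed-batch feeding, or realistic covariance
between reference-measurement errors. Passing recovery tests therefore
demonstrates the pipeline's correctness under the linear-mixing assumption
with realistic noise magnitudes — not performance on any particular real
instrument.

## Problem sizes and numerics

The default synthetic run used by tests and the acceptance script is
361 spectra × 1627 channels (truncated to 852 by the online recipes) with
12 calibration samples, chosen to match the monitored campaign's cadence
and schedule; the whole pipeline runs in seconds. Tolerances: EMSC/PLSR
oracle agreement at 1e−8 relative; rubber-band second-pass baseline ≤ 1e−10
relative; degenerate-fit threshold 1e−10 on the EMSC scale factor.
Tie-breaks: component selection prefers fewer components; nearest-spectrum
alignment prefers the earlier spectrum; PCA signs fix the largest-magnitude
loading element positive.

## Known limitations

* The rubber-band correction is the plain convex hull; spectra whose true
  background is non-convex (strong curved fluorescence) keep a residual.
* EMSC assumes the mean spectrum is a sensible reference; early-vs-late
  composition drift biases b slightly (visible as a constant offset factor
  in scatter recovery, harmless after calibration).
* PLS1 only — one analyte per model; multi-response PLS2 is out of scope.
* Reported CV metrics on 12 samples carry large sampling variance; the
  cross-replicate validation path exists precisely to catch optimism.
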