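"""Rubber-band baseline, Savitzky-Golay, peak normalization, EMSC, recipes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanpat import (
    BUILTIN_RECIPES,
    PreprocessRecipe,
    SpectraSet,
    Spectrum,
    apply_recipe,
    emsc,
    peak_normalize,
    rubberband_baseline,
    savitzky_golay,
)
from ramanpat.errors import (
    DegenerateFitError,
    NormalizationError,
    ParameterError,
    ValidationError,
)
from ramanpat.preprocess import _legendre_basis


def brute_force_lower_hull(x, y):
    """O(n^2) lower-hull oracle: a point is a hull vertex iff no chord
    between any two other points passes strictly below it ... equivalently,
    the baseline at each x is the maximum over all chords lying at or below
    every data point. Computed here as the pointwise maximum of all
    admissible chords, which equals the lower convex hull."""
    n = x.size
    base = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            # chord through points i and j
            slope = (y[j] - y[i]) / (x[j] - x[i])
            chord = y[i] + slope * (x - x[i])
            if np.all(chord <= y + 1e-9 * (1 + np.abs(y))):
                base = np.maximum(base, chord)
    return base


class TestRubberband:
    def test_zero_signal_gives_zero_baseline(self):
        s = Spectrum(np.linspace(1800, 800, 50), np.zeros(50))
        corr, base = rubberband_baseline(s)
        assert np.all(corr.intensities == 0) and np.all(base.intensities == 0)

    def test_gaussian_on_slope_recovers_gaussian(self):
        w = np.linspace(2000, 1000, 301)
        slope_line = 0.002 * w + 1.0
        peak = 5.0 * np.exp(-((w - 1500.0) ** 2) / (2 * 30.0**2))
        corr, base = rubberband_baseline(Spectrum(w, slope_line + peak))
        np.testing.assert_allclose(base.intensities, slope_line, atol=1e-8)
        np.testing.assert_allclose(corr.intensities, peak, atol=1e-8)

    def test_matches_brute_force_hull_on_random_spectra(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 60))
            w = np.sort(rng.uniform(500, 3500, n))[::-1]
            y = rng.normal(0, 1, n) + 0.1 * np.abs(w - w.mean()) / 100
            s = Spectrum(w, y)
            _, base = rubberband_baseline(s)
            oracle = brute_force_lower_hull(w[::-1], y[::-1])[::-1]
            np.testing.assert_allclose(base.intensities, oracle, atol=1e-7)

    def test_convex_smile_residual_vs_hull_oracle(self):
        w = np.linspace(1600, 1200, 101)
        y = 1e-4 * (w - 1400.0) ** 2  # opens upward: hull = polyline close to curve
        corr, base = rubberband_baseline(Spectrum(w, y))
        oracle = brute_force_lower_hull(w[::-1], y[::-1])[::-1]
        np.testing.assert_allclose(base.intensities, oracle, atol=1e-8)
        assert corr.intensities[0] == pytest.approx(0.0, abs=1e-10)
        assert corr.intensities[-1] == pytest.approx(0.0, abs=1e-10)

    def test_idempotent_and_baseline_below_signal(self, random_spectrum):
        corr, base = rubberband_baseline(random_spectrum)
        assert np.all(base.intensities <= random_spectrum.intensities + 1e-9)
        _, base2 = rubberband_baseline(corr)
        assert np.max(np.abs(base2.intensities)) <= 1e-10 * max(
            1.0, np.max(np.abs(corr.intensities))
        )

    def test_too_few_channels(self):
        with pytest.raises(ValidationError):
            rubberband_baseline(Spectrum([800.0, 700.0], [1.0, 2.0]))


class TestSavitzkyGolay:
    def test_constant_signal_unchanged(self):
        s = Spectrum(np.linspace(1800, 800, 60), np.full(60, 3.14))
        out = savitzky_golay(s, 9, 2, 0)
        np.testing.assert_allclose(out.intensities, 3.14, atol=1e-12)

    def test_quadratic_reproduced_everywhere(self):
        w = np.linspace(2000, 1000, 81)
        y = 1e-6 * w**2 - 3e-3 * w + 1.0
        out = savitzky_golay(Spectrum(w, y), 9, 2, 0)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-9)

    def test_second_derivative_of_nu_squared_is_two(self):
        w = np.linspace(2000, 1000, 101)  # uniform, descending
        out = savitzky_golay(Spectrum(w, w**2), 9, 2, 2)
        np.testing.assert_allclose(out.intensities[4:-4], 2.0, rtol=1e-8)

    def test_first_derivative_sign_follows_increasing_wavenumber(self):
        w = np.linspace(2000, 1000, 101)
        out = savitzky_golay(Spectrum(w, 3.0 * w), 9, 2, 1)
        np.testing.assert_allclose(out.intensities[4:-4], 3.0, rtol=1e-8)

    def test_interior_matches_scipy(self, random_spectrum):
        from scipy.signal import savgol_filter

        out = savitzky_golay(random_spectrum, 11, 3, 0)
        ref = savgol_filter(random_spectrum.intensities, 11, 3)
        np.testing.assert_allclose(out.intensities[5:-5], ref[5:-5], atol=1e-10)

    def test_smoothing_preserves_mean_of_noisy_constant(self, rng):
        n = 4000
        s = Spectrum(np.linspace(4000, 400, n), 5.0 + rng.normal(0, 0.5, n))
        out = savitzky_golay(s, 9, 2, 0)
        se = 0.5 / np.sqrt(n)
        assert abs(out.intensities.mean() - 5.0) < 3 * se

    @pytest.mark.parametrize("window,polyorder,deriv", [(8, 2, 0), (5, 5, 0), (9, 2, 3)])
    def test_illegal_parameters(self, window, polyorder, deriv):
        s = Spectrum(np.linspace(1800, 800, 30), np.ones(30))
        with pytest.raises(ParameterError):
            savitzky_golay(s, window, polyorder, deriv)


class TestPeakNormalize:
    def test_scale_invariance_and_idempotence(self, random_spectrum):
        s = Spectrum(random_spectrum.wavenumbers, np.abs(random_spectrum.intensities) + 0.1)
        a = peak_normalize(s, 1500, 20)
        b = peak_normalize(Spectrum(s.wavenumbers, 7.5 * s.intensities), 1500, 20)
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-12)
        again = peak_normalize(a, 1500, 20)
        np.testing.assert_allclose(again.intensities, a.intensities, rtol=1e-12)

    def test_divides_by_window_maximum(self):
        w = np.linspace(900, 700, 201)
        y = np.ones(201)
        y[np.argmin(np.abs(w - 810))] = 5.0
        out = peak_normalize(Spectrum(w, y), 800, 16)
        np.testing.assert_allclose(out.intensities.max(), 1.0)
        assert out.intensities[np.argmin(np.abs(w - 810))] == pytest.approx(1.0)

    def test_offset_peak_found_within_window(self):
        w = np.linspace(900, 700, 401)
        y = 2.0 * np.exp(-((w - 802.0) ** 2) / (2 * 8.0**2))
        out = peak_normalize(Spectrum(w, y), 800, 10)
        # independent argmax oracle inside the window
        mask = (w >= 790) & (w <= 810)
        peak_idx = np.flatnonzero(mask)[np.argmax(y[mask])]
        assert out.intensities[peak_idx] == pytest.approx(1.0)

    def test_nonpositive_window_max_rejected(self):
        s = Spectrum(np.linspace(900, 700, 50), -np.ones(50))
        with pytest.raises(NormalizationError):
            peak_normalize(s, 800, 16)


class TestEmsc:
    @pytest.fixture
    def axis(self):
        return np.linspace(1800, 800, 120)

    def test_reference_is_fixed_point(self, axis, rng):
        ref = Spectrum(axis, np.abs(rng.normal(2, 0.5, axis.size)))
        s = SpectraSet(axis, ref.intensities[None, :], [0.0])
        res = emsc(s, reference=ref, degree=3)
        assert res.multiplicative[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(res.additive[0], 0.0, atol=1e-9)
        np.testing.assert_allclose(res.corrected.intensities[0], ref.intensities, atol=1e-9)

    def test_exact_model_recovered(self, axis, rng):
        ref = Spectrum(axis, np.abs(rng.normal(2, 0.5, axis.size)))
        s = SpectraSet(axis, (2.0 * ref.intensities + 3.0)[None, :], [0.0])
        res = emsc(s, reference=ref, degree=2)
        assert res.multiplicative[0] == pytest.approx(2.0, rel=1e-10)
        assert res.additive[0, 0] == pytest.approx(3.0, rel=1e-9)  # constant term
        np.testing.assert_allclose(res.corrected.intensities[0], ref.intensities, rtol=1e-9)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        w = np.linspace(1500, 1000, 20)
        Y = rng.normal(1.0, 0.3, size=(6, 20))
        ref = Spectrum(w, np.abs(rng.normal(1, 0.2, 20)) + 0.5)
        res = emsc(SpectraSet(w, Y, np.arange(6.0)), reference=ref, degree=2)
        D = np.column_stack([ref.intensities, _legendre_basis(w, 2)])
        for i in range(6):
            coef_oracle = np.linalg.solve(D.T @ D, D.T @ Y[i])
            got = np.concatenate([[res.multiplicative[i]], res.additive[i]])
            np.testing.assert_allclose(got, coef_oracle, rtol=1e-8)
            resid = Y[i] - D @ coef_oracle
            # residual orthogonal to every design column
            assert np.max(np.abs(D.T @ resid)) < 1e-8 * np.linalg.norm(Y[i])

    def test_mean_reference_default(self, small_set):
        res = emsc(small_set, degree=2)
        np.testing.assert_allclose(
            res.reference.intensities, small_set.intensities.mean(axis=0)
        )

    def test_degenerate_scale_rejected(self, axis):
        ref = Spectrum(axis, np.sin(axis / 50.0) + 2.0)
        flat = SpectraSet(axis, np.zeros((1, axis.size)), [0.0])
        with pytest.raises(DegenerateFitError):
            emsc(flat, reference=ref, degree=1)


class TestRecipes:
    def test_empty_recipe_is_identity(self, small_set):
        out = apply_recipe(small_set, PreprocessRecipe("noop", []))
        np.testing.assert_array_equal(out.intensities, small_set.intensities)

    @pytest.mark.parametrize(
        "name,kinds",
        [
            ("online_glass", ["rubberband", "savgol", "peak_normalize", "truncate"]),
            ("online_water", ["rubberband", "savgol", "peak_normalize", "truncate"]),
            ("online_emsc_d4", ["rubberband", "savgol", "truncate", "emsc"]),
            ("online_emsc_d6", ["rubberband", "savgol", "truncate", "emsc"]),
            ("hts_ftir", ["savgol", "truncate", "emsc"]),
            ("hts_raman", ["savgol", "truncate", "rubberband", "emsc"]),
        ],
    )
    def test_builtin_step_orders(self, name, kinds):
        assert [k for k, _ in BUILTIN_RECIPES[name].steps] == kinds

    def test_builtin_parameters(self):
        glass = dict(BUILTIN_RECIPES["online_glass"].steps)
        assert glass["peak_normalize"]["anchor"] == 800
        assert glass["savgol"] == {"window": 9, "polyorder": 2, "deriv": 0}
        assert glass["truncate"]["regions"] == [(3050, 2500), (1800, 650)]
        ftir = dict(BUILTIN_RECIPES["hts_ftir"].steps)
        assert ftir["savgol"] == {"window": 15, "polyorder": 2, "deriv": 2}
        assert ftir["truncate"]["regions"] == [(3050, 2800), (1800, 900)]
        assert ftir["emsc"]["degree"] == 2
        assert dict(BUILTIN_RECIPES["online_emsc_d4"].steps)["emsc"]["degree"] == 4
        assert dict(BUILTIN_RECIPES["online_emsc_d6"].steps)["emsc"]["degree"] == 6
        assert dict(BUILTIN_RECIPES["online_water"].steps)["peak_normalize"]["anchor"] == 3200

    def test_yaml_roundtrip_deterministic(self):
        r = BUILTIN_RECIPES["online_glass"]
        text = r.to_yaml()
        back = PreprocessRecipe.from_yaml(text)
        assert back.name == r.name
        assert [k for k, _ in back.steps] == [k for k, _ in r.steps]
        assert back.to_yaml() == text

    def test_apply_recipe_deterministic(self, small_set):
        r = PreprocessRecipe(
            "t",
            [("rubberband", {}), ("savgol", {"window": 9, "polyorder": 2, "deriv": 0}),
             ("emsc", {"degree": 2})],
        )
        a = apply_recipe(small_set, r)
        b = apply_recipe(small_set, r)
        assert np.array_equal(a.intensities, b.intensities)  # bit-identical

    def test_step_errors_annotated_with_index(self, small_set):
        r = PreprocessRecipe("bad", [("savgol", {"window": 8, "polyorder": 2, "deriv": 0})])
        with pytest.raises(ParameterError, match="step 0"):
            apply_recipe(small_set, r)

    def test_provenance_recorded(self, rng):
        w = np.linspace(3785, 650, 400)
        wide_set = SpectraSet(w, np.abs(rng.normal(1.0, 0.2, size=(4, 400))), np.arange(4.0))
        out = apply_recipe(wide_set, BUILTIN_RECIPES["hts_raman"])
        assert out.labels["recipe"] == "hts_raman"
        assert [s["kind"] for s in out.labels["steps"]] == [
            "savgol", "truncate", "rubberband", "emsc"
        ]

    def test_unknown_step_kind_rejected(self):
        with pytest.raises(ParameterError):
            PreprocessRecipe("x", [("despike", {})])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_rubberband_idempotence_property(seed):
    """Second-pass rubber-band baseline of a corrected spectrum is ~zero."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 80))
    w = np.sort(rng.uniform(400, 4000, n))[::-1]
    y = rng.normal(0, 1, n)
    corr, _ = rubberband_baseline(Spectrum(w, y))
    _, base2 = rubberband_baseline(corr)
    assert np.max(np.abs(base2.intensities)) <= 1e-9 * max(1.0, np.abs(y).max())
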