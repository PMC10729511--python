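"""High-level orchestration: calibrate, monitor, and cross-validate runs.

These functions tie the preprocessing recipes, spectra/reference alignment
and PLSR calibration together the way a monitoring campaign uses them:

* :func:`calibrate_run` — preprocess an online series, align it to the
  offline reference table, run leave-one-out CV per analyte and fit one
  calibration model per analyte at its optimal component count.
* :func:`monitor_run` — predict every analyte at every acquisition
  timestamp of a (new or same) series: the real-time concentration profile.
* :func:`validate_run` — apply fitted models unchanged to an independent
  replicate (control vs loop reactor) and report test metrics.

Rows with a missing reference value are dropped per analyte, not globally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .chemometrics import (
    CalibrationModel,
    ValidationReport,
    calibrate,
    check_units,
    plsr_predict,
    r2_score,
    render_pct,
    rmse,
    rmse_pct_of_max,
)
from .errors import RamanPatError
from .preprocess import PreprocessRecipe, apply_recipe
from .spectra import ReferenceTable, SpectraSet, align_to_reference

__all__ = ["calibrate_run", "monitor_run", "validate_run", "calibration_report"]

log = logging.getLogger("ramanpat")


def calibrate_run(
    spectra: SpectraSet,
    ref: ReferenceTable,
    recipe: PreprocessRecipe,
    analytes: list[str] | None = None,
    policy: str = "mean",
    window_h: float = 0.5,
    A_max: int | None = None,
) -> dict[str, CalibrationModel]:
    """One PLSR calibration model per analyte.

    The whole series is preprocessed with the recipe first (so set-level
    steps such as the EMSC mean reference see every spectrum), then aligned
    to the reference sampling timepoints.
    """
    processed = apply_recipe(spectra, recipe)
    X, ref, matched = align_to_reference(processed, ref, window_h=window_h, policy=policy)
    models: dict[str, CalibrationModel] = {}
    for analyte in analytes or ref.analytes:
        y = ref.column(analyte)
        keep = np.isfinite(y)
        m = calibrate(
            X[keep],
            y[keep],
            analyte=analyte,
            units=ref.unit_of(analyte),
            recipe=recipe,
            A_max=A_max,
        )
        m.provenance.update(
            {
                "policy": policy,
                "window_h": window_h,
                "matched_times": [matched[i] for i in np.nonzero(keep)[0]],
            }
        )
        models[analyte] = m
    return models


def calibration_report(models: dict[str, CalibrationModel]) -> pd.DataFrame:
    """Per-analyte table mirroring standard calibration reporting: range,
    R²_CV (Aopt), RMSE_CV with its percent-of-range-maximum."""
    rows = []
    for analyte, m in models.items():
        a = m.A
        rmse_cv = float(m.cv_rmse[a - 1])
        pct = rmse_pct_of_max(rmse_cv, [m.y_train_max])
        rows.append(
            {
                "analyte": analyte,
                "units": m.units,
                "n": m.n_train,
                "range_max": m.y_train_max,
                "r2_cv": float(m.cv_r2[a - 1]),
                "Aopt": a,
                "rmse_cv": rmse_cv,
                "rmse_pct_of_max": pct,
                "rendered": f"{rmse_cv:.2f} ({render_pct(pct)})",
            }
        )
    return pd.DataFrame(rows)


def monitor_run(
    models: dict[str, CalibrationModel],
    spectra: SpectraSet,
) -> pd.DataFrame:
    """Predicted concentration profile: one row per (timestamp, analyte).

    Spectra that fail a recipe step are skipped with a log message rather
    than aborting the profile — online series can contain gaps and corrupt
    acquisitions.
    """
    frames = []
    for analyte, m in models.items():
        if m.recipe is None:
            raise RamanPatError(f"model for {analyte!r} carries no preprocessing recipe")
        try:
            processed = apply_recipe(spectra, m.recipe)
            times = processed.times
            X = processed.intensities
        except RamanPatError:
            # fall back to per-spectrum processing, skipping failures
            rows, times_ok = [], []
            for i in range(spectra.n_spectra):
                single = SpectraSet(
                    spectra.wavenumbers,
                    spectra.intensities[i : i + 1],
                    spectra.times[i : i + 1],
                )
                try:
                    done = apply_recipe(single, m.recipe)
                except RamanPatError as exc:
                    log.warning(
                        "skipping spectrum at t=%.3f h for %s: %s",
                        spectra.times[i], analyte, exc,
                    )
                    continue
                rows.append(done.intensities[0])
                times_ok.append(spectra.times[i])
            if not rows:
                raise
            X = np.vstack(rows)
            times = np.asarray(times_ok)
        y_hat = plsr_predict(m, X)
        frames.append(
            pd.DataFrame(
                {"time_h": times, "analyte": analyte, "units": m.units, "value": y_hat}
            )
        )
    return pd.concat(frames, ignore_index=True)


def validate_run(
    models: dict[str, CalibrationModel],
    test_spectra: SpectraSet,
    test_ref: ReferenceTable,
    policy: str = "mean",
    window_h: float = 0.5,
) -> list[ValidationReport]:
    """Apply fitted models unchanged to an independent bioreplicate."""
    reports = []
    for analyte, m in models.items():
        check_units(m, test_ref)
        processed = apply_recipe(test_spectra, m.recipe)
        X, _, _ = align_to_reference(processed, test_ref, window_h=window_h, policy=policy)
        y = test_ref.column(analyte)
        keep = np.isfinite(y)
        y_hat = plsr_predict(m, X[keep])
        e = rmse(y[keep], y_hat)
        reports.append(
            ValidationReport(
                analyte=analyte,
                units=m.units,
                r2=r2_score(y[keep], y_hat),
                rmse=e,
                rmse_pct_of_max=rmse_pct_of_max(e, y[keep]),
                n=int(keep.sum()),
                kind="test",
            )
        )
    return reports
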