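"""PLSR calibration, cross-validation, and model-quality metrics.

Partial least squares regression (PLS1, NIPALS) links the preprocessed
spectral matrix X (n samples × p channels) to one analyte y at a time. Model
complexity (the number of latent components, Aopt) is chosen by
leave-one-out ("one-sample-out") cross-validation, minimizing RMSE_CV, with
ties broken toward fewer components. X and y are mean-centered, never
variance-scaled, so RMSE is reported in native analyte units; the
relative-RMSE convention (100·RMSE / max reference value, rendered round
half-up to one decimal) matches standard chemometric reporting of
calibration tables.

R² is the prediction-based 1 − SSE/SST form throughout, which can go
negative in cross-validation when the model predicts worse than the mean.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, RankError, UnitMismatchError, ValidationError
from .preprocess import PreprocessRecipe
from .spectra import ReferenceTable

__all__ = [
    "CalibrationModel",
    "ValidationReport",
    "plsr_fit",
    "plsr_predict",
    "loo_cv",
    "select_components",
    "r2_score",
    "rmse",
    "rmse_pct_of_max",
    "render_pct",
    "validate_on_test",
    "calibrate",
    "pca",
    "correlation_matrix",
]


@dataclass
class CalibrationModel:
    """A fitted PLS1 calibration for a single analyte.

    Prediction uses the collapsed regression vector: ŷ = y_mean +
    (X − x_mean)·coefficients, which agrees with sequential score-deflation
    prediction to numerical precision.
    """

    analyte: str
    units: str
    A: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (A, p) NIPALS weight vectors w_a
    x_loadings: np.ndarray   # (A, p) loadings p_a
    y_loadings: np.ndarray   # (A,)   loadings q_a
    coefficients: np.ndarray  # (p,) regression vector in centered space
    recipe: PreprocessRecipe | None = None
    cv_rmse: np.ndarray | None = None
    cv_r2: np.ndarray | None = None
    n_train: int | None = None
    y_train_max: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        doc = {
            "analyte": self.analyte,
            "units": self.units,
            "A": int(self.A),
            "x_mean": arr(self.x_mean),
            "y_mean": float(self.y_mean),
            "weights": arr(self.weights),
            "x_loadings": arr(self.x_loadings),
            "y_loadings": arr(self.y_loadings),
            "coefficients": arr(self.coefficients),
            "recipe": None if self.recipe is None else yaml_recipe(self.recipe),
            "cv_rmse": arr(self.cv_rmse),
            "cv_r2": arr(self.cv_r2),
            "n_train": self.n_train,
            "y_train_max": self.y_train_max,
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        doc = json.loads(text)

        def arr(key):
            v = doc[key]
            return None if v is None else np.asarray(v, dtype=float)

        recipe = None
        if doc["recipe"] is not None:
            recipe = PreprocessRecipe.from_yaml(doc["recipe"])
        return cls(
            analyte=doc["analyte"],
            units=doc["units"],
            A=doc["A"],
            x_mean=arr("x_mean"),
            y_mean=doc["y_mean"],
            weights=arr("weights"),
            x_loadings=arr("x_loadings"),
            y_loadings=arr("y_loadings"),
            coefficients=arr("coefficients"),
            recipe=recipe,
            cv_rmse=arr("cv_rmse"),
            cv_r2=arr("cv_r2"),
            n_train=doc["n_train"],
            y_train_max=doc["y_train_max"],
            provenance=doc.get("provenance", {}),
        )


def yaml_recipe(recipe: PreprocessRecipe) -> str:
    return recipe.to_yaml()


@dataclass
class ValidationReport:
    """R², RMSE and relative RMSE of a model on CV or an external test set."""

    analyte: str
    units: str
    r2: float
    rmse: float
    rmse_pct_of_max: float
    n: int
    kind: str  # "cv" | "test"

    def rendered_pct(self) -> str:
        return render_pct(self.rmse_pct_of_max)


# --- PLS1 NIPALS ----------------------------------------------------------

def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, A: int):
    """NIPALS PLS1 on centered data; returns (W, P, q) with rows per component."""
    n, p = Xc.shape
    W = np.empty((A, p))
    P = np.empty((A, p))
    q = np.empty(A)
    X = Xc.copy()
    y = yc.copy()
    for a in range(A):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise RankError(f"component {a + 1}: no covariance left to extract")
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-28:
            raise RankError(f"component {a + 1}: degenerate score vector")
        pa = (X.T @ t) / tt
        qa = (y @ t) / tt
        X = X - np.outer(t, pa)
        y = y - qa * t
        W[a], P[a], q[a] = w, pa, qa
    return W, P, q


def _collapse_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # B = W (P W^T)^{-1} q  with W, P stored rows-per-component
    A = W.shape[0]
    R = np.linalg.solve(P @ W.T, np.eye(A))
    return W.T @ (R @ q)


def plsr_fit(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    *,
    analyte: str = "",
    units: str = "",
    recipe: PreprocessRecipe | None = None,
) -> CalibrationModel:
    """Fit a PLS1 model with A components on mean-centered X, y.

    No variance scaling is applied; y stays in native units. Scores of
    distinct components are mutually orthogonal and the training residual is
    non-increasing in A.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("X/y contain NaN; drop or impute before fitting")
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"X has {n} rows but y has {y.size} values")
    if np.ptp(y) == 0:
        raise DegenerateFitError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    rank = np.linalg.matrix_rank(Xc)
    if A > min(n - 1, rank):
        raise RankError(f"A={A} exceeds usable rank {min(n - 1, rank)}")
    W, P, q = _nipals_pls1(Xc, y - y_mean, A)
    coef = _collapse_coefficients(W, P, q)
    return CalibrationModel(
        analyte=analyte,
        units=units,
        A=A,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        recipe=recipe,
        n_train=n,
        y_train_max=float(y.max()),
    )


def plsr_predict(m: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """ŷ = y_mean + (X − x_mean) · coefficients."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.x_mean.size:
        raise ValidationError(
            f"model expects {m.x_mean.size} channels, X has {X.shape[1]}"
        )
    return m.y_mean + (X - m.x_mean) @ m.coefficients


# --- metrics --------------------------------------------------------------

def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Prediction R² = 1 − SSE/SST (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    sse = np.sum((y_pred - y_true) ** 2)
    sst = np.sum((y_true - y_true.mean()) ** 2)
    if sst == 0:
        raise DegenerateFitError("y_true has zero variance; R² undefined")
    return float(1.0 - sse / sst)


def rmse_pct_of_max(rmse_value: float, ref_values) -> float:
    """RMSE as a percentage of the largest reference value."""
    ref = np.asarray(ref_values, dtype=float)
    m = np.nanmax(ref)
    if not m > 0:
        raise ValueError(f"maximum reference value must be positive, got {m}")
    return 100.0 * float(rmse_value) / float(m)


def render_pct(pct: float, decimals: int = 1) -> str:
    """Round half-up to ``decimals`` and render with a trailing %, e.g. '3.4%'."""
    q = Decimal(10) ** -decimals
    return f"{Decimal(repr(float(pct))).quantize(q, rounding=ROUND_HALF_UP)}%"


# --- cross-validation -----------------------------------------------------

def loo_cv(X: np.ndarray, y: np.ndarray, A_max: int | None = None):
    """Leave-one-out CV curves: (rmse_cv, r2_cv), each indexed by A-1.

    Every fold refits from scratch on the remaining n−1 samples,
    re-centering X and y inside the fold, then predicts the held-out sample.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValidationError("leave-one-out CV needs at least 3 samples")
    if A_max is None:
        A_max = min(10, n - 2)
    if A_max > n - 2:
        raise RankError(f"A_max={A_max} exceeds n-2={n - 2}")
    preds = np.empty((A_max, n))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xi, yi = X[keep], y[keep]
        if np.ptp(yi) == 0:
            raise DegenerateFitError(f"fold {i}: training y has zero variance")
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        Xc = Xi - x_mean
        rank_i = np.linalg.matrix_rank(Xc)
        a_hi = min(A_max, Xi.shape[0] - 1, rank_i)
        W, P, q = _nipals_pls1(Xc, yi - y_mean, a_hi)
        for a in range(1, A_max + 1):
            aa = min(a, a_hi)
            coef = _collapse_coefficients(W[:aa], P[:aa], q[:aa])
            preds[a - 1, i] = y_mean + (X[i] - x_mean) @ coef
    sst = np.sum((y - y.mean()) ** 2)
    rmse_cv = np.sqrt(np.mean((preds - y) ** 2, axis=1))
    r2_cv = 1.0 - np.sum((preds - y) ** 2, axis=1) / sst
    return rmse_cv, r2_cv


def select_components(rmse_cv) -> int:
    """Aopt = argmin RMSE_CV, ties toward the smaller component count."""
    rmse_cv = np.asarray(rmse_cv, dtype=float)
    if rmse_cv.size == 0:
        raise ValueError("empty RMSE_CV curve")
    return int(np.argmin(rmse_cv)) + 1  # argmin returns the first minimum


def calibrate(
    X: np.ndarray,
    y: np.ndarray,
    *,
    analyte: str = "",
    units: str = "",
    recipe: PreprocessRecipe | None = None,
    A_max: int | None = None,
) -> CalibrationModel:
    """Full calibration: LOO-CV curve → Aopt → final fit on all samples."""
    rmse_cv, r2_cv = loo_cv(X, y, A_max)
    A = select_components(rmse_cv)
    m = plsr_fit(X, y, A, analyte=analyte, units=units, recipe=recipe)
    m.cv_rmse = rmse_cv
    m.cv_r2 = r2_cv
    m.provenance["x_sha256"] = hashlib.sha256(
        np.ascontiguousarray(X, dtype=float).tobytes()
    ).hexdigest()
    return m


def validate_on_test(m: CalibrationModel, X_test, y_test) -> ValidationReport:
    """Apply the model unchanged to an independent test set."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size == 0:
        raise ValidationError("empty test set")
    y_hat = plsr_predict(m, X_test)
    e = rmse(y_test, y_hat)
    return ValidationReport(
        analyte=m.analyte,
        units=m.units,
        r2=r2_score(y_test, y_hat),
        rmse=e,
        rmse_pct_of_max=rmse_pct_of_max(e, y_test),
        n=y_test.size,
        kind="test",
    )


def check_units(m: CalibrationModel, ref: ReferenceTable) -> None:
    unit = ref.unit_of(m.analyte)
    if unit != m.units:
        raise UnitMismatchError(
            f"model for {m.analyte!r} is in {m.units!r} but reference table declares {unit!r}"
        )


# --- PCA ------------------------------------------------------------------

def pca(X: np.ndarray, k: int):
    """Mean-centered PCA via SVD.

    Returns (scores, loadings, explained_variance_fractions) with loadings of
    shape (k, p), orthonormal rows, each flipped so its largest-magnitude
    element is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise RankError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    scores = U[:, :k] * sv[:k]
    total_var = np.sum(sv**2)
    frac = sv[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
    return scores, Vt[:k], frac


# --- Pearson correlations -------------------------------------------------

def correlation_matrix(ref: ReferenceTable, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the reference analytes.

    Cells with fewer than ``min_pairs`` complete pairs or a zero-variance
    series are NaN (flagged as undefined, never silently zero).
    """
    df = pd.DataFrame(ref.values, columns=ref.analytes, index=ref.timepoints)
    corr = df.corr(method="pearson", min_periods=min_pairs)
    degenerate = df.std(ddof=1) == 0
    for name in df.columns[degenerate]:
        corr.loc[name, :] = np.nan
        corr.loc[:, name] = np.nan
    return corr
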