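"""Calibration fit metrics and leave-one-out cross-validation.

RMSEC (error of calibration) is the root mean squared training residual
with denominator n; RMSEP (error of prediction) is the same statistic over
the held-out predictions of leave-one-out cross-validation, in which the
centering and the PLS1 fit are re-estimated inside every fold (range
cutting and derivative filtering act per spectrum, hence are
fold-invariant and may be done once).

R-squared is reported in both common variants, labeled: the coefficient of
determination 1 - SS_res/SS_tot, and the squared Pearson correlation
between measured and fitted values as read off a calibration plot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .preprocess import (DEFAULT_RANGES, DEFAULT_SG_POLYORDER,
                         DEFAULT_SG_WINDOW, cut_ranges,
                         savgol_second_derivative)
from .pls import PLS1Model, fit_pls1, predict
from .spectra import SpectrumSet


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error, denominator n."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_true.size < 1:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray,
              kind: str = "ss") -> float:
    """R^2 as 1 - SS_res/SS_tot (``kind='ss'``) or squared Pearson
    correlation (``kind='corr'``)."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance reference values")
    if kind == "ss":
        return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    if kind == "corr":
        if np.std(y_pred) == 0.0:
            return 0.0
        return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    raise ValueError(f"unknown R^2 kind {kind!r}")


def calibration_metrics(model: PLS1Model, X: np.ndarray, y: np.ndarray,
                        a: int | None = None) -> tuple[float, float]:
    """(R2_cal, RMSEC) of a fitted model on its training data.

    R2_cal is 1 - SS_res/SS_tot; the null model (``a = 0``) therefore gives
    exactly 0.
    """
    fitted = predict(model, X, a=a)
    return r_squared(y, fitted, kind="ss"), rmse(y, fitted)


def loocv(features: np.ndarray, y: np.ndarray,
          n_components: int) -> tuple[np.ndarray, float, float]:
    """Leave-one-out cross-validation on (uncentered) derivative features.

    For each sample the centering and PLS1 fit are redone on the other
    n - 1 samples and the held-out spectrum predicted. Returns
    (held-out predictions, RMSEP, R2_pred).
    """
    X = np.asarray(features, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = fit_pls1(X[mask], y[mask], n_components, keep_scores=False)
        preds[i] = predict(m, X[i]).item()
        mask[i] = True
    return preds, rmse(y, preds), r_squared(y, preds, kind="ss")


# ---------------------------------------------------------------------------
# report over the three macromolecular pools
# ---------------------------------------------------------------------------

@dataclass
class ModelValidation:
    """Fit and LOOCV statistics for one response."""

    response: str
    n_samples: int
    n_components: int
    R2_cal: float
    R2_cal_corr: float
    RMSEC: float
    RMSEP: float
    R2_pred: float
    R2_pred_corr: float
    loocv_predictions: np.ndarray
    x_variance_pct: np.ndarray
    y_variance_pct: np.ndarray

    def __post_init__(self) -> None:
        if self.loocv_predictions.size != self.n_samples:
            raise ValueError("LOOCV prediction count must equal n_samples")


@dataclass
class ValidationReport:
    """Per-macromolecule validation results plus the fitted models."""

    per_response: dict[str, ModelValidation]
    models: dict[str, PLS1Model] = field(default_factory=dict)

    def to_table(self, top_bands: int = 3) -> pd.DataFrame:
        """Model-summary table: one row per macromolecular pool."""
        rows = []
        for name, v in self.per_response.items():
            row = {
                "response": name,
                "n_calibration_spectra": v.n_samples,
                "R2": round(v.R2_cal, 4),
                "R2_corr": round(v.R2_cal_corr, 4),
                "RMSEC_pctDW": round(v.RMSEC, 4),
                "RMSEP_pctDW": round(v.RMSEP, 4),
                "R2_pred": round(v.R2_pred, 4),
                "n_factors": v.n_components,
                "x_variance_explained_pct":
                    round(float(v.x_variance_pct.sum()), 2),
                "y_variance_explained_pct":
                    round(float(v.y_variance_pct.sum()), 2),
            }
            model = self.models.get(name)
            if model is not None and model.wavenumbers is not None:
                coef = np.abs(model.B[:, model.n_components - 1])
                idx = np.argsort(coef)[::-1][:top_bands]
                row["top_predictor_bands_cm-1"] = ";".join(
                    f"{model.wavenumbers[i]:g}" for i in sorted(idx))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict[str, Any]:
        return {name: {
            "n_samples": v.n_samples,
            "n_components": v.n_components,
            "R2_cal": v.R2_cal, "R2_cal_corr": v.R2_cal_corr,
            "RMSEC": v.RMSEC, "RMSEP": v.RMSEP,
            "R2_pred": v.R2_pred, "R2_pred_corr": v.R2_pred_corr,
            "loocv_predictions": v.loocv_predictions.tolist(),
            "x_variance_pct": v.x_variance_pct.tolist(),
            "y_variance_pct": v.y_variance_pct.tolist(),
        } for name, v in self.per_response.items()}

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def validate_calibration(
    raw: SpectrumSet,
    compositions: pd.DataFrame,
    responses: Sequence[str] = ("protein", "lipid", "carbohydrate"),
    n_components: int = 7,
    ranges=DEFAULT_RANGES,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
) -> ValidationReport:
    """Preprocess a raw calibration set and fit + validate one PLS1 model
    per requested macromolecular pool."""
    deriv = savgol_second_derivative(cut_ranges(raw, ranges),
                                          window, polyorder)
    features = deriv.absorbance
    wavenumbers = deriv.wavenumbers
    seg_lengths = [s.size for s in deriv.segments]
    provenance = {"ranges": [list(r) for r in ranges], "sg_window": window,
                  "sg_polyorder": polyorder}

    per_response: dict[str, ModelValidation] = {}
    models: dict[str, PLS1Model] = {}
    order = [str(c["id"]) for _, c in raw.meta.iterrows()]
    comp = compositions.loc[order]
    for name in responses:
        y = comp[name].to_numpy(float)
        model = fit_pls1(features, y, n_components, wavenumbers=wavenumbers,
                         segment_lengths=seg_lengths, response=name)
        model.preprocessing = dict(provenance,
                                   training_mean=features.mean(axis=0).tolist())
        fitted = predict(model, features)
        preds, rmsep, r2_pred = loocv(features, y, n_components)
        per_response[name] = ModelValidation(
            response=name, n_samples=len(y),
            n_components=model.n_components,
            R2_cal=r_squared(y, fitted, "ss"),
            R2_cal_corr=r_squared(y, fitted, "corr"),
            RMSEC=rmse(y, fitted), RMSEP=rmsep, R2_pred=r2_pred,
            R2_pred_corr=r_squared(y, preds, "corr"),
            loocv_predictions=preds,
            x_variance_pct=model.x_variance_pct,
            y_variance_pct=model.y_variance_pct)
        models[name] = model
    return ValidationReport(per_response=per_response, models=models)
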