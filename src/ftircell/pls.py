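"""PLS1 regression via the orthogonal-scores (NIPALS) algorithm.

One model is calibrated per macromolecular pool (PLS1, single response),
exactly the classical orthogonal-scores recursion: for component
a = 1..A on the deflated blocks (X_a, y_a),

    w_a = X_a' y_a / ||X_a' y_a||          (unit-norm weight)
    t_a = X_a w_a                          (score)
    p_a = X_a' t_a / (t_a' t_a)            (x-loading)
    q_a = y_a' t_a / (t_a' t_a)            (y-loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a

Score vectors are mutually orthogonal; the regression coefficient vector
for any truncation a is B_a = W_a (P_a' W_a)^{-1} q_a, applied to centered
data: yhat = y_mean + (x - x_mean) B_a.

X and y are centered internally (the means are stored on the model); no
variance scaling is applied, matching a preprocessing chain that ends in
plain mean centering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

SERIALIZATION_VERSION = 1

#: relative threshold on ||X_a' y_a|| below which deflation has exhausted
#: the covariance and extraction stops early.
_DEGENERACY_RTOL = 1e-12


class RankWarning(UserWarning):
    """Emitted when deflation exhausts X'y before the requested components."""


@dataclass
class PLS1Model:
    """Fitted PLS1 calibration for one response (% dry weight).

    ``B[:, a-1]`` is the coefficient vector using the first ``a``
    components; ``n_components`` is the achieved count (may be below the
    request if deflation exhausted the covariance early).
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray                   # [p x A] unit-norm weights
    P: np.ndarray                   # [p x A] x-loadings
    q: np.ndarray                   # [A] y-loadings
    B: np.ndarray                   # [p x A], column a-1 = B_a
    x_variance_pct: np.ndarray      # [A] per-component % of ||Xc||_F^2
    y_variance_pct: np.ndarray      # [A] per-component % of ||yc||^2
    T: np.ndarray | None = None     # [n x A] training scores
    wavenumbers: np.ndarray | None = None
    segment_lengths: list[int] | None = None
    response: str = ""
    requested_components: int | None = None
    preprocessing: dict[str, Any] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.x_mean.size

    def training_fitted(self) -> np.ndarray:
        if self.T is None:
            raise ValueError("training scores were not persisted")
        return self.y_mean + self.T @ self.q


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    wavenumbers: np.ndarray | None = None,
    segment_lengths: list[int] | None = None,
    response: str = "",
    keep_scores: bool = True,
) -> PLS1Model:
    """Fit a PLS1 model with up to ``n_components`` orthogonal-score factors.

    ``X`` may be raw or centered; both blocks are centered internally and
    the means stored. Raises on zero-variance ``y`` or when
    ``n_components`` exceeds ``min(n - 1, p)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X rows and y length differ")
    A = int(n_components)
    if A < 1:
        raise ValueError("n_components must be >= 1")
    if A > min(n - 1, p):
        raise ValueError(
            f"n_components = {A} exceeds min(n - 1, p) = {min(n - 1, p)} "
            f"for n = {n} samples, p = {p} features")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = X - x_mean
    ya = y - y_mean
    ss_x = float(np.sum(Xa * Xa))
    ss_y = float(np.sum(ya * ya))
    if ss_y == 0.0:
        raise ValueError("zero-variance response y")

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    xvar = np.zeros(A)
    yvar = np.zeros(A)
    cov_scale = float(np.linalg.norm(X.T @ (y - y_mean))) or 1.0

    achieved = 0
    for a in range(A):
        w = Xa.T @ ya
        nw = float(np.linalg.norm(w))
        if nw <= _DEGENERACY_RTOL * cov_scale:
            warnings.warn(
                f"X'y vanished after {achieved} components "
                f"(requested {A}); stopping early", RankWarning,
                stacklevel=2)
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        pa = (Xa.T @ t) / tt
        qa = float(ya @ t) / tt
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        xvar[a] = tt * float(pa @ pa) / ss_x * 100.0
        yvar[a] = qa * qa * tt / ss_y * 100.0
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        achieved = a + 1

    if achieved == 0:
        raise ValueError("could not extract any component (X'y is zero)")
    W, P, T, q = W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved]
    xvar, yvar = xvar[:achieved], yvar[:achieved]

    B = np.zeros((p, achieved))
    R = P.T @ W   # upper-triangular with unit-ish diagonal in exact NIPALS
    for a in range(1, achieved + 1):
        B[:, a - 1] = W[:, :a] @ np.linalg.solve(R[:a, :a], q[:a])

    return PLS1Model(
        n_components=achieved, x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q,
        B=B, x_variance_pct=xvar, y_variance_pct=yvar,
        T=T if keep_scores else None,
        wavenumbers=None if wavenumbers is None
        else np.asarray(wavenumbers, float),
        segment_lengths=list(segment_lengths) if segment_lengths else None,
        response=response, requested_components=A)


def predict(model: PLS1Model, X_new: np.ndarray,
            a: int | None = None) -> np.ndarray:
    """Predict % DW responses: yhat = y_mean + (X_new - x_mean) B_a.

    ``a`` picks the component count (defaults to the model's); ``a = 0`` is
    the null model returning ``y_mean`` for every row.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: model has {model.n_features}, input has "
            f"{X_new.shape[1]}")
    if a is None:
        a = model.n_components
    if a < 0 or a > model.n_components:
        raise ValueError(f"a must be in [0, {model.n_components}]")
    if a == 0:
        return np.full(X_new.shape[0], model.y_mean)
    return model.y_mean + (X_new - model.x_mean) @ model.B[:, a - 1]


def regression_coefficient_spectrum(model: PLS1Model,
                                    a: int) -> pd.DataFrame:
    """Coefficient vector B_a mapped onto the retained wavenumber axis.

    Returns a DataFrame (wavenumber, coefficient, segment) whose segment
    column preserves the gap structure of the cut ranges for plotting.
    """
    if not 1 <= a <= model.n_components:
        raise ValueError(f"a must be in [1, {model.n_components}]")
    if model.wavenumbers is None:
        raise ValueError("model was fitted without a wavenumber axis")
    coef = model.B[:, a - 1]
    seg_lengths = model.segment_lengths or [model.n_features]
    seg_ids = np.repeat(np.arange(len(seg_lengths)), seg_lengths)
    return pd.DataFrame({"wavenumber_cm-1": model.wavenumbers,
                         "coefficient": coef, "segment": seg_ids})


def explained_variance(model: PLS1Model) -> tuple[np.ndarray, np.ndarray]:
    """Per-component explained variance (%) for the X block and y block."""
    return model.x_variance_pct.copy(), model.y_variance_pct.copy()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: PLS1Model) -> dict[str, Any]:
    return {
        "version": SERIALIZATION_VERSION,
        "response": model.response,
        "n_components": model.n_components,
        "requested_components": model.requested_components,
        "y_mean": model.y_mean,
        "x_mean": model.x_mean.tolist(),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "B": model.B.tolist(),
        "x_variance_pct": model.x_variance_pct.tolist(),
        "y_variance_pct": model.y_variance_pct.tolist(),
        "wavenumbers": None if model.wavenumbers is None
        else model.wavenumbers.tolist(),
        "segment_lengths": model.segment_lengths,
        "preprocessing": model.preprocessing,
    }


def model_from_dict(d: dict[str, Any]) -> PLS1Model:
    if d.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model version {d.get('version')!r}")
    return PLS1Model(
        n_components=int(d["n_components"]),
        x_mean=np.asarray(d["x_mean"], float),
        y_mean=float(d["y_mean"]),
        W=np.asarray(d["W"], float), P=np.asarray(d["P"], float),
        q=np.asarray(d["q"], float), B=np.asarray(d["B"], float),
        x_variance_pct=np.asarray(d["x_variance_pct"], float),
        y_variance_pct=np.asarray(d["y_variance_pct"], float),
        T=None,
        wavenumbers=None if d.get("wavenumbers") is None
        else np.asarray(d["wavenumbers"], float),
        segment_lengths=d.get("segment_lengths"),
        response=d.get("response", ""),
        requested_components=d.get("requested_components"),
        preprocessing=d.get("preprocessing", {}))


def save_model(model: PLS1Model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> PLS1Model:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
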