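"""PLS regression engine and model-building workflow.

The calibration workflow mirrors standard chemometric practice for
mid-IR quantification: spectra are pretreated by a frozen
:class:`~stalkscreen.preprocess.PreprocessRecipe`, mean centred, and
regressed on reference values with partial least squares.  Latent
variable (LV) count is chosen by leave-one-out cross-validation; an
optional jackknife confidence-interval filter removes wavenumbers
whose regression coefficients are statistically indistinguishable from
zero; and a bias correction (offset plus optional slope factor)
estimated from the cross-validation predicted-versus-reference line is
applied to predictions.

Two fitting algorithms are provided and must agree:

* ``nipals`` — the classical non-linear iterative partial least
  squares deflation algorithm, initialised from the response column of
  maximal variance (iteration tolerance 1e-12, at most 500 iterations
  per LV).
* ``wide_kernel`` — the association-matrix (XX', YY') kernel variant
  suited to wide matrices (many more wavenumbers than samples).

Both assemble regression coefficients as B = W (PᵀW)⁻¹ Qᵀ, so their
predictions coincide to numerical precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from stalkscreen.preprocess import PreprocessRecipe, apply_center, fit_center
from stalkscreen.spectra import SpectraSet, align_to_grid

MODEL_SCHEMA_VERSION = "stalkscreen-pls-1"

_TOL = 1e-12
_MAX_ITER = 500
_EPS = 1e-300


@dataclass
class ModelMetrics:
    """Error and fit statistics in target units (RMSE*) or dimensionless."""

    rmsec: float | None = None
    rmsecv: float | None = None
    rmsep: float | None = None
    r2: float | None = None
    q2: float | None = None
    bias: float | None = None
    slope: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class BiasCorrection:
    """Offset (target units) and dimensionless slope factor.

    corrected = (raw − offset) · slope_factor
    """

    offset: float = 0.0
    slope_factor: float = 1.0

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.offset) * self.slope_factor


# ---------------------------------------------------------------------------
# core fitting


def _validate_fit_inputs(X: np.ndarray, Y: np.ndarray, n_lv: int) -> None:
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("NaN in inputs")
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(
            f"n_lv out of bounds: {n_lv} not in [1, {min(n - 1, p)}]")


def _nipals_decompose(Xc: np.ndarray, Yc: np.ndarray, n_lv: int):
    """NIPALS deflation on centred blocks → (W, P, Q, T)."""
    X = Xc.copy()
    Y = Yc.copy()
    p = X.shape[1]
    m = Y.shape[1]
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    Q = np.empty((m, n_lv))
    T = np.empty((X.shape[0], n_lv))
    for k in range(n_lv):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        converged = False
        for _ in range(_MAX_ITER):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw < _EPS:
                raise ValueError("rank exhausted: cannot extract further LVs")
            w /= nw
            t = X @ w
            tt = t @ t
            if tt < _EPS:
                raise ValueError("rank exhausted: degenerate score vector")
            q = Y.T @ t / tt
            if m == 1:
                converged = True
                break
            u_new = Y @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= _TOL * max(np.linalg.norm(u_new), 1e-30):
                u = u_new
                converged = True
                break
            u = u_new
        if not converged:
            raise ValueError("NIPALS failed to converge")
        pk = X.T @ t / tt
        X = X - np.outer(t, pk)
        Y = Y - np.outer(t, q)
        W[:, k], P[:, k], Q[:, k], T[:, k] = w, pk, q, t
    return W, P, Q, T


def _wide_kernel_decompose(Xc: np.ndarray, Yc: np.ndarray, n_lv: int):
    """Association-matrix kernel PLS on centred blocks → (W, P, Q, T)."""
    XX = Xc @ Xc.T
    YY = Yc @ Yc.T
    XXd = XX.copy()
    YYd = YY.copy()
    n = Xc.shape[0]
    T = np.empty((n, n_lv))
    U = np.empty((n, n_lv))
    for k in range(n_lv):
        start = int(np.argmax(np.diag(YYd)))
        t = XXd @ YYd[:, start]
        nt = np.linalg.norm(t)
        if nt < _EPS:
            raise ValueError("rank exhausted: cannot extract further LVs")
        t /= nt
        converged = False
        for _ in range(_MAX_ITER):
            t_new = XXd @ (YYd @ t)
            nt = np.linalg.norm(t_new)
            if nt < _EPS:
                raise ValueError("rank exhausted: degenerate score vector")
            t_new /= nt
            if t_new @ t < 0:
                t_new = -t_new
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta <= _TOL:
                converged = True
                break
        if not converged:
            raise ValueError("wide-kernel PLS failed to converge")
        u = YYd @ t
        T[:, k] = t
        U[:, k] = u
        for M in (XXd, YYd):
            Mt = M @ t
            M -= np.outer(t, t @ M)
            M -= np.outer(M @ t, t)
    W = Xc.T @ U
    norms = np.linalg.norm(W, axis=0)
    if np.any(norms < _EPS):
        raise ValueError("rank exhausted: degenerate weight vector")
    W /= norms
    P = Xc.T @ T  # scores are orthonormal
    Q = Yc.T @ T
    return W, P, Q, T


def _coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray,
                  k: int) -> np.ndarray:
    """B = W_k (P_kᵀ W_k)⁻¹ Q_kᵀ, shape (p, m)."""
    Wk, Pk, Qk = W[:, :k], P[:, :k], Q[:, :k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, Qk.T)


@dataclass
class PLSModel:
    """Fitted PLS predictor with its frozen preprocessing and bias terms.

    ``grid`` is the wavenumber axis after preprocessing (before the
    variable mask); ``variable_mask`` selects the retained wavenumbers.
    """

    targets: list[str]
    n_lv: int
    algorithm: str
    x_means: np.ndarray
    y_means: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    grid: np.ndarray | None = None
    variable_mask: np.ndarray | None = None
    recipe: PreprocessRecipe | None = None
    bias: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    training_metrics: dict = field(default_factory=dict)
    calibration_range: dict = field(default_factory=dict)

    def predict_matrix(self, X: np.ndarray, bias_corrected: bool = True) -> np.ndarray:
        """Predict from an already-preprocessed, masked matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        raw = apply_center(X, self.x_means) @ self.coefficients + self.y_means
        if not bias_corrected:
            return raw
        out = raw.copy()
        for j, t in enumerate(self.targets):
            corr = self.bias.get(t)
            if corr is not None:
                out[:, j] = corr.apply(out[:, j])
        return out

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Latent-variable scores T = Xc W (PᵀW)⁻¹ for a masked matrix."""
        Xc = apply_center(np.atleast_2d(np.asarray(X, dtype=float)), self.x_means)
        R = self.x_weights @ np.linalg.inv(self.x_loadings.T @ self.x_weights)
        return Xc @ R


def fit_pls(X: np.ndarray, Y: np.ndarray, n_lv: int,
            algorithm: str = "nipals") -> PLSModel:
    """Fit a PLS model on preprocessed X against reference Y.

    Deterministic: NIPALS starts from the Y column of maximal variance;
    both algorithms agree in their predictions to numerical precision.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    targets = None
    if hasattr(Y, "columns"):  # pragma: no cover - defensive
        targets = [str(c) for c in Y.columns]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    _validate_fit_inputs(X, Y, n_lv)
    x_means = fit_center(X)
    y_means = fit_center(Y)
    Xc = X - x_means
    Yc = Y - y_means
    if algorithm == "nipals":
        W, P, Q, T = _nipals_decompose(Xc, Yc, n_lv)
    elif algorithm == "wide_kernel":
        W, P, Q, T = _wide_kernel_decompose(Xc, Yc, n_lv)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    B = _coefficients(W, P, Q, n_lv)
    if targets is None:
        targets = [f"y{j}" for j in range(Y.shape[1])]
    model = PLSModel(
        targets=targets, n_lv=n_lv, algorithm=algorithm,
        x_means=x_means, y_means=y_means,
        x_weights=W, x_loadings=P, y_loadings=Q, coefficients=B,
    )
    pred = model.predict_matrix(X, bias_corrected=False)
    for j, t in enumerate(targets):
        model.training_metrics[t] = regression_metrics(
            pred[:, j], Y[:, j], context="calibration")
    return model


# ---------------------------------------------------------------------------
# cross-validation, LV selection, variable filtering


@dataclass
class CVResult:
    """Leave-one-out results: RMSECV per LV and pooled out-of-fold predictions."""

    rmsecv: np.ndarray          # (max_lv, m)
    oof_predictions: np.ndarray  # (max_lv, n, m)
    references: np.ndarray       # (n, m)


def cross_validate(X: np.ndarray, Y: np.ndarray, max_lv: int,
                   scheme: str = "loo") -> CVResult:
    """Full (leave-one-out) cross-validation: n refits, pooled predictions."""
    if scheme != "loo":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError("too few samples for cross-validation")
    if not 1 <= max_lv <= min(n - 2, p):
        raise ValueError("max_lv out of bounds for leave-one-out folds")
    m = Y.shape[1]
    oof = np.empty((max_lv, n, m))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt, Yt = X[keep], Y[keep]
        xm = Xt.mean(axis=0)
        ym = Yt.mean(axis=0)
        W, P, Q, _ = _nipals_decompose(Xt - xm, Yt - ym, max_lv)
        xc = X[i] - xm
        for k in range(1, max_lv + 1):
            oof[k - 1, i] = xc @ _coefficients(W, P, Q, k) + ym
    rmsecv = np.sqrt(((oof - Y[None]) ** 2).mean(axis=1))
    return CVResult(rmsecv=rmsecv, oof_predictions=oof, references=Y)


def select_n_lv(rmsecv_table: np.ndarray, parsimony_tol: float = 0.01) -> int:
    """Smallest LV count whose RMSECV is within ``parsimony_tol`` of the minimum.

    Ties break toward fewer LVs.
    """
    r = np.asarray(rmsecv_table, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("empty RMSECV table")
    best = r.min()
    within = np.nonzero(r <= best * (1.0 + parsimony_tol))[0]
    return int(within[0]) + 1


def jackknife_ci_filter(X: np.ndarray, Y: np.ndarray, n_lv: int,
                        alpha: float = 0.10) -> np.ndarray:
    """Variable mask keeping wavenumbers whose coefficient CI excludes 0.

    Martens' jackknife over leave-one-out refits: for each variable,
    variance = ((n−1)/n)·Σ(b_i − b̄)² and a normal-approximation CI at
    level 1−alpha around the full-data coefficient.  With multiple
    targets a variable is kept if significant for any target.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError("too few samples for jackknife")
    full = fit_pls(X, Y, n_lv)
    b_full = full.coefficients  # (p, m)
    boots = np.empty((n, p, Y.shape[1]))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        sub = fit_pls(X[keep], Y[keep], n_lv)
        boots[i] = sub.coefficients
    var = (n - 1) / n * ((boots - boots.mean(axis=0)) ** 2).sum(axis=0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    keep_mask = (np.abs(b_full) > half).any(axis=1)
    if not keep_mask.any():
        raise ValueError("empty model: all variables removed by CI filter")
    return keep_mask


def calibrate_bias(out_of_fold_predictions: np.ndarray,
                   references: np.ndarray,
                   slope_dead_band: float = 0.01) -> BiasCorrection:
    """Offset/slope bias terms from the CV predicted-versus-reference line.

    OLS fit pred = a + b·ref; offset = a (removes any constant
    background), slope_factor = 1/b applied only when |b − 1| exceeds
    the dead band.
    """
    pred = np.asarray(out_of_fold_predictions, dtype=float).ravel()
    ref = np.asarray(references, dtype=float).ravel()
    if pred.size != ref.size:
        raise ValueError("prediction/reference length mismatch")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs for bias calibration")
    if np.ptp(ref) == 0:
        raise ValueError("degenerate bias fit: constant reference")
    b, a = np.polyfit(ref, pred, 1)
    slope_factor = 1.0 / b if abs(b - 1.0) > slope_dead_band else 1.0
    return BiasCorrection(offset=float(a), slope_factor=float(slope_factor))


# ---------------------------------------------------------------------------
# prediction and diagnostics


@dataclass
class PredictionResult:
    """Per-sample target predictions with negative-value flags."""

    sample_ids: list[str]
    targets: list[str]
    values: np.ndarray           # (n, m), bias-corrected
    negative_flags: np.ndarray   # (n, m) bool

    def as_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.values, columns=self.targets)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def predict(model: PLSModel, sset: SpectraSet) -> PredictionResult:
    """Apply frozen recipe, variable mask, coefficients, then bias terms.

    Negative concentration predictions are reported as-is and flagged,
    never clamped (clamping would distort error statistics).
    """
    processed = sset if model.recipe is None else model.recipe.apply(sset)
    if model.grid is not None:
        if processed.grid.size != model.grid.size or not np.allclose(
                processed.grid, model.grid):
            processed = align_to_grid(processed, model.grid)
    X = processed.matrix
    if model.variable_mask is not None:
        X = X[:, model.variable_mask]
    if X.shape[1] != model.x_means.size:
        raise ValueError("grid not coverable: wavenumber count mismatch")
    values = model.predict_matrix(X, bias_corrected=True)
    return PredictionResult(
        sample_ids=list(sset.sample_ids), targets=list(model.targets),
        values=values, negative_flags=values < 0)


def regression_metrics(predictions: np.ndarray, references: np.ndarray,
                       context: str = "calibration") -> ModelMetrics:
    """RMSE and coefficient of determination, labelled per context.

    ``calibration`` fills RMSEC/R²; ``validation`` fills RMSEP/Q².
    R²/Q² = 1 − SSE/SStot about the reference mean.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    ref = np.asarray(references, dtype=float).ravel()
    if pred.size != ref.size:
        raise ValueError("prediction/reference length mismatch")
    if pred.size < 2:
        raise ValueError("need at least 2 pairs")
    err = pred - ref
    rmse = float(np.sqrt(np.mean(err ** 2)))
    sstot = float(((ref - ref.mean()) ** 2).sum())
    r2 = 1.0 - float((err ** 2).sum()) / sstot if sstot > 0 else float("nan")
    mean_bias = float(err.mean())
    slope = float(np.polyfit(ref, pred, 1)[0]) if np.ptp(ref) > 0 else float("nan")
    if context == "calibration":
        return ModelMetrics(rmsec=rmse, r2=r2, bias=mean_bias, slope=slope)
    if context == "validation":
        return ModelMetrics(rmsep=rmse, q2=r2, bias=mean_bias, slope=slope)
    raise ValueError(f"unknown context {context!r}")


@dataclass
class OutlierReport:
    """Residual/leverage diagnostics; flags are advisory, removal is manual."""

    sample_ids: list[str]
    residual_distance: np.ndarray  # |studentized y-residual|, (n,) or (n, m)
    leverage: np.ndarray
    flagged: np.ndarray
    reasons: list[str]


def detect_outliers(model: PLSModel, X: np.ndarray, Y: np.ndarray,
                    residual_z: float = 3.0,
                    leverage_mult: float = 3.0,
                    sample_ids: list[str] | None = None) -> OutlierReport:
    """Flag calibration samples by studentized residual or leverage.

    Leverage h_i = 1/n + t_iᵀ(TᵀT)⁻¹t_i (intercept convention: the
    leverages sum to n_lv + 1).  Threshold: h > leverage_mult·(n_lv+1)/n.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    T = model.scores(X)
    h = 1.0 / n + np.einsum("ij,ji->i", T, np.linalg.solve(T.T @ T, T.T))
    resid = Y - model.predict_matrix(X, bias_corrected=False)
    s = np.sqrt((resid ** 2).sum(axis=0) / max(n - model.n_lv - 1, 1))
    s = np.where(s > 0, s, 1.0)
    stud = np.abs(resid) / (s[None, :] * np.sqrt(np.clip(1.0 - h, 1e-12, None))[:, None])
    stud_max = stud.max(axis=1)
    h_thresh = leverage_mult * (model.n_lv + 1) / n
    flag_resid = stud_max > residual_z
    flag_lev = h > h_thresh
    flagged = flag_resid | flag_lev
    reasons = []
    for fr, fl in zip(flag_resid, flag_lev):
        if fr and fl:
            reasons.append("residual+leverage")
        elif fr:
            reasons.append("residual")
        elif fl:
            reasons.append("leverage")
        else:
            reasons.append("")
    ids = sample_ids or [str(i) for i in range(n)]
    return OutlierReport(sample_ids=ids, residual_distance=stud_max,
                         leverage=h, flagged=flagged, reasons=reasons)


def estimate_lod(model: PLSModel, blank_spectra: SpectraSet,
                 factor: float = 3.3) -> dict:
    """Limit of detection per target: 3.3 × SD of bias-corrected blank predictions.

    One admissible (ICH-style) reading of a lower limit of detection
    for an inverse-calibration model; requires ≥ 10 blank spectra.
    """
    if blank_spectra.n_samples < 10:
        raise ValueError("too few blanks: need at least 10")
    pred = predict(model, blank_spectra).values
    sd = pred.std(axis=0, ddof=1)
    return {t: float(factor * sd[j]) for j, t in enumerate(model.targets)}


# ---------------------------------------------------------------------------
# serialization


def _arr(x):
    return None if x is None else np.asarray(x)


def save_model(model: PLSModel, path) -> None:
    """Serialize a PLSModel (recipe included) to versioned JSON."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "targets": model.targets,
        "units": model.units,
        "n_lv": model.n_lv,
        "algorithm": model.algorithm,
        "x_means": model.x_means.tolist(),
        "y_means": model.y_means.tolist(),
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "grid": None if model.grid is None else model.grid.tolist(),
        "variable_mask": None if model.variable_mask is None
        else model.variable_mask.astype(int).tolist(),
        "recipe": None if model.recipe is None else model.recipe.to_dict(),
        "bias": {t: {"offset": b.offset, "slope_factor": b.slope_factor}
                 for t, b in model.bias.items()},
        "training_metrics": {t: m.to_dict()
                             for t, m in model.training_metrics.items()},
        "calibration_range": model.calibration_range,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> PLSModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file: {exc}") from None
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unknown model schema version {doc.get('schema_version')!r}")
    model = PLSModel(
        targets=list(doc["targets"]),
        n_lv=int(doc["n_lv"]),
        algorithm=doc["algorithm"],
        x_means=np.asarray(doc["x_means"], dtype=float),
        y_means=np.asarray(doc["y_means"], dtype=float),
        x_weights=np.asarray(doc["x_weights"], dtype=float),
        x_loadings=np.asarray(doc["x_loadings"], dtype=float),
        y_loadings=np.asarray(doc["y_loadings"], dtype=float),
        coefficients=np.asarray(doc["coefficients"], dtype=float),
        grid=None if doc["grid"] is None else np.asarray(doc["grid"], dtype=float),
        variable_mask=None if doc["variable_mask"] is None
        else np.asarray(doc["variable_mask"], dtype=bool),
        recipe=None if doc["recipe"] is None
        else PreprocessRecipe.from_dict(doc["recipe"]),
        bias={t: BiasCorrection(**b) for t, b in doc.get("bias", {}).items()},
        units=dict(doc.get("units", {})),
        calibration_range=dict(doc.get("calibration_range", {})),
    )
    model.training_metrics = {t: ModelMetrics(**m) for t, m in
                              doc.get("training_metrics", {}).items()}
    return model


# ---------------------------------------------------------------------------
# high-level workflow


def calibrate_model(sset: SpectraSet, target: str,
                    recipe: PreprocessRecipe,
                    algorithm: str = "nipals",
                    n_lv: int | None = None,
                    max_lv: int = 15,
                    ci_filter_alpha: float | None = None,
                    slope_dead_band: float = 0.01,
                    unit: str = "") -> PLSModel:
    """Full single-target calibration workflow.

    recipe → (optional jackknife CI variable filter + refit) →
    leave-one-out CV → LV selection (unless ``n_lv`` is given) → final
    fit → bias calibration from the out-of-fold predictions.
    """
    if sset.reference is None or target not in sset.reference.columns:
        raise ValueError(f"calibration set has no reference for {target!r}")
    processed = recipe.fit(sset)
    X = processed.matrix
    y = sset.reference[target].to_numpy(dtype=float)[:, None]
    max_lv = min(max_lv, X.shape[0] - 2, X.shape[1])

    mask = np.ones(X.shape[1], dtype=bool)
    if ci_filter_alpha is not None:
        pre_lv = n_lv if n_lv is not None else select_n_lv(
            cross_validate(X, y, max_lv).rmsecv[:, 0])
        mask = jackknife_ci_filter(X, y, pre_lv, alpha=ci_filter_alpha)
        X = X[:, mask]

    cv_max = min(max_lv, X.shape[1])
    cv = cross_validate(X, y, cv_max)
    chosen = n_lv if n_lv is not None else select_n_lv(cv.rmsecv[:, 0])
    if chosen > cv_max:
        raise ValueError("n_lv out of bounds after variable filtering")
    model = fit_pls(X, y, chosen, algorithm=algorithm)
    model.targets = [target]
    model.training_metrics = {target: model.training_metrics.pop("y0")}
    model.units = {target: unit}
    model.grid = processed.grid.copy()
    model.variable_mask = mask
    model.recipe = recipe
    model.bias = {target: calibrate_bias(cv.oof_predictions[chosen - 1, :, 0],
                                         y[:, 0], slope_dead_band)}
    metrics = model.training_metrics[target]
    metrics.rmsecv = float(cv.rmsecv[chosen - 1, 0])
    model.training_metrics = {target: metrics}
    model.calibration_range = {target: [float(y.min()), float(y.max())]}
    return model
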