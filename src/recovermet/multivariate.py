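"""PCA and orthogonal PLS discriminant analysis (OPLS-DA).

The discriminant model is a from-scratch O-PLS for a single centered +/-1
class response: predictor variance is split into one predictive component
(covarying with class) and up to three orthogonal components (class-
uncorrelated structure removed by deflation before the final predictive
fit). Model quality is summarized by in-fit R2Y and stratified 7-fold
cross-validated Q2 = 1 - PRESS/SS; stability by a label-permutation test
with the add-one p-value estimator. Per-feature importance is the
predictive-component VIP, ``sqrt(J) * |w_j|`` for unit-norm weights, whose
squares average to exactly 1.

Algorithm per orthogonal round (NIPALS-style for one y):

    w  = X'y / ||X'y||        predictive weights
    t  = Xw                   predictive scores
    p  = X't / t't            loadings
    w_o = p - (w'p) w         orthogonal weights (normalized)
    t_o = X w_o;  p_o = X't_o / t_o't_o
    X <- X - t_o p_o'         deflate and repeat

after which the predictive component is refit on the deflated matrix. With
zero orthogonal components the model is exactly a one-component PLS1.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import MetabolomicsDataset


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA


@dataclasses.dataclass
class PcaModel:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: pd.Series


def _as_matrix(data) -> tuple[np.ndarray, list, list]:
    if isinstance(data, MetabolomicsDataset):
        df = data.abundance
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        arr = np.asarray(data, dtype=float)
        return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def pca_fit(data, n_components: int) -> PcaModel:
    """Mean-centered SVD with a deterministic sign convention (the largest-
    magnitude loading element of each component is made positive)."""
    X, row_ids, col_ids = _as_matrix(data)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components > max_comp:
        raise ModelError(f"n_components {n_components} exceeds min(n-1, p) = {max_comp}")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(n_components):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    total = float(np.sum(s**2))
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    comp = [f"PC{k + 1}" for k in range(n_components)]
    return PcaModel(
        scores=pd.DataFrame(u[:, :n_components] * s[:n_components], index=row_ids, columns=comp),
        loadings=pd.DataFrame(vt[:n_components].T, index=col_ids, columns=comp),
        explained_variance_fraction=pd.Series(frac, index=comp),
    )


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclasses.dataclass
class PermutationRecord:
    n_perm: int
    q2_observed: float
    q2_permuted: np.ndarray
    r2y_permuted: np.ndarray
    p_value: float


@dataclasses.dataclass
class OplsModel:
    """Fitted O-PLS discriminant model (single predictive component)."""

    w: np.ndarray                 # predictive weights, unit norm
    t_pred: np.ndarray            # predictive scores
    p_pred: np.ndarray            # predictive loadings
    p_corr: np.ndarray            # corr(feature, t_pred): S-plot y axis
    w_ortho: np.ndarray           # (n_ortho, J)
    p_ortho: np.ndarray
    t_ortho: np.ndarray           # (n, n_ortho)
    n_ortho: int
    b: float                      # regression of centered y on t_pred
    x_mean: np.ndarray
    y_mean: float
    classes: tuple                # (negative class, positive class)
    r2y: float
    q2: float
    vip: pd.Series
    feature_names: list
    cv_folds: int
    seed: int
    metadata: dict = dataclasses.field(default_factory=dict)
    permutation: PermutationRecord | None = None

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Predictive score for new observations (orthogonal structure
        removed with the training components first)."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        for k in range(self.n_ortho):
            t_o = Xc @ self.w_ortho[k]
            Xc = Xc - np.outer(t_o, self.p_ortho[k])
        return Xc @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction on the centered +/-1 scale + mean."""
        return self.b * self.predict_score(X) + self.y_mean


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ModelError(f"need exactly two classes, got {classes.tolist()}")
    coded = np.where(y == classes[1], 1.0, -1.0)
    return coded, (classes[0], classes[1])


def _fit_core(Xc: np.ndarray, yc: np.ndarray, n_ortho: int):
    """O-PLS on centered data; returns (w, t, p, W_o, P_o, T_o)."""
    X = Xc.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = X.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ModelError("zero covariance between X and y")
        w = w / norm
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-12:
            break  # no orthogonal structure left
        w_o = w_o / norm_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = X.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ModelError("zero covariance between X and y")
    w = w / norm
    t = X @ w
    p = X.T @ t / (t @ t)
    return w, t, p, W_o, P_o, T_o


def _cv_q2(X: np.ndarray, coded: np.ndarray, n_ortho: int,
           cv_folds: int, seed: int) -> float:
    """Stratified K-fold Q2 = 1 - PRESS/SS_tot, fold assignment seeded."""
    counts = np.unique(coded, return_counts=True)[1]
    if counts.min() < cv_folds:
        raise ModelError(
            f"each class needs >= cv_folds={cv_folds} members for stratified CV")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    press = 0.0
    y_mean_all = coded.mean()
    ss_tot = float(np.sum((coded - y_mean_all) ** 2))
    for train, test in skf.split(X, coded):
        x_mean = X[train].mean(axis=0)
        y_mean = coded[train].mean()
        Xc = X[train] - x_mean
        yc = coded[train] - y_mean
        w, t, p, W_o, P_o, _ = _fit_core(Xc, yc, n_ortho)
        b = float(t @ yc / (t @ t))
        Xt = X[test] - x_mean
        for w_o, p_o in zip(W_o, P_o):
            t_o = Xt @ w_o
            Xt = Xt - np.outer(t_o, p_o)
        y_hat = b * (Xt @ w) + y_mean
        press += float(np.sum((coded[test] - y_hat) ** 2))
    return 1.0 - press / ss_tot


def opls_fit(X, y, n_ortho: int | str = "auto", cv_folds: int = 7,
             seed: int = 0, max_ortho: int = 3,
             q2_improvement: float = 0.01) -> OplsModel:
    """Fit OPLS-DA for a binary response.

    ``n_ortho="auto"`` adds orthogonal components while CV Q2 improves by
    more than ``q2_improvement`` (at most ``max_ortho``); an integer fixes
    the count (0 reduces to one-component PLS1). X should already carry the
    upstream scaling (the pipeline passes the Pareto matrix); only centering
    is applied here.
    """
    Xm, _, feature_names = _as_matrix(X)
    coded, classes = _encode_labels(y)

    if n_ortho == "auto":
        chosen = 0
        best_q2 = _cv_q2(Xm, coded, 0, cv_folds, seed)
        for k in range(1, max_ortho + 1):
            q2_k = _cv_q2(Xm, coded, k, cv_folds, seed)
            if q2_k - best_q2 > q2_improvement:
                chosen, best_q2 = k, q2_k
            else:
                break
        n_ortho_final, q2 = chosen, best_q2
    else:
        n_ortho_final = int(n_ortho)
        q2 = _cv_q2(Xm, coded, n_ortho_final, cv_folds, seed) if cv_folds else np.nan

    x_mean = Xm.mean(axis=0)
    y_mean = float(coded.mean())
    Xc = Xm - x_mean
    yc = coded - y_mean
    w, t, p, W_o, P_o, T_o = _fit_core(Xc, yc, n_ortho_final)
    b = float(t @ yc / (t @ t))
    y_hat = b * t
    ss_res = float(np.sum((yc - y_hat) ** 2))
    ss_tot = float(np.sum(yc**2))
    r2y = 1.0 - ss_res / ss_tot

    if np.isfinite(q2) and q2 > r2y:
        warnings.warn(f"Q2 ({q2:.3f}) exceeds R2Y ({r2y:.3f}); "
                      "cross-validation may be unstable", stacklevel=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        sd = Xc.std(axis=0, ddof=1)
        cov = Xc.T @ t / (len(t) - 1)
        p_corr = np.where(sd > 0, cov / (sd * t.std(ddof=1)), 0.0)

    J = Xm.shape[1]
    vip = pd.Series(np.sqrt(J) * np.abs(w), index=feature_names, name="vip")

    return OplsModel(
        w=w, t_pred=t, p_pred=p, p_corr=p_corr,
        w_ortho=np.array(W_o) if W_o else np.empty((0, J)),
        p_ortho=np.array(P_o) if P_o else np.empty((0, J)),
        t_ortho=np.array(T_o).T if T_o else np.empty((Xm.shape[0], 0)),
        n_ortho=len(W_o), b=b, x_mean=x_mean, y_mean=y_mean, classes=classes,
        r2y=r2y, q2=q2, vip=vip, feature_names=list(feature_names),
        cv_folds=cv_folds, seed=seed,
        metadata={"vip_variant": "predictive", "class_coding": "+/-1 centered"},
    )


def vip_scores(model: OplsModel) -> pd.Series:
    """Predictive-component VIP: ``sqrt(J) * |w_j|``; mean of VIP^2 is 1."""
    return model.vip


def opls_permutation_test(X, y, n_perm: int = 200, seed: int = 0,
                          cv_folds: int = 7,
                          model: OplsModel | None = None) -> PermutationRecord:
    """Label-permutation stability test.

    The class vector is relabelled uniformly at random ``n_perm`` times and
    the model refit with the same settings (orthogonal-component count fixed
    at the observed model's resolved value); the p-value uses the add-one
    estimator ``(1 + #{Q2_perm >= Q2_obs}) / (1 + n_perm)``, so ``n_perm=0``
    degenerates to p = 1.
    """
    Xm, _, _ = _as_matrix(X)
    if model is None:
        model = opls_fit(Xm, y, n_ortho="auto", cv_folds=cv_folds, seed=seed)
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    q2_perm, r2y_perm = [], []
    for _ in range(n_perm):
        y_shuffled = rng.permutation(y)
        try:
            m = opls_fit(Xm, y_shuffled, n_ortho=model.n_ortho,
                         cv_folds=cv_folds, seed=seed)
            q2_perm.append(m.q2)
            r2y_perm.append(m.r2y)
        except ModelError:
            # a permutation that breaks stratification counts as uninformative
            q2_perm.append(-np.inf)
            r2y_perm.append(np.nan)
    q2_perm_arr = np.asarray(q2_perm, dtype=float)
    p = (1 + int(np.sum(q2_perm_arr >= model.q2))) / (1 + n_perm)
    record = PermutationRecord(
        n_perm=n_perm, q2_observed=model.q2, q2_permuted=q2_perm_arr,
        r2y_permuted=np.asarray(r2y_perm, dtype=float), p_value=p,
    )
    model.permutation = record
    return record


def splot_coordinates(model: OplsModel, X) -> pd.DataFrame:
    """S-plot coordinates: per-feature covariance with the predictive score
    (n-1 convention) on x, Pearson correlation on y (zero-variance features
    get correlation 0 and a flag)."""
    Xm, _, names = _as_matrix(X)
    Xc = Xm - Xm.mean(axis=0)
    t = model.t_pred
    n = len(t)
    cov = Xc.T @ (t - t.mean()) / (n - 1)
    sd = Xc.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(zero_var, 0.0, cov / (sd * t.std(ddof=1)))
    return pd.DataFrame(
        {"covariance": cov, "correlation": corr, "zero_variance": zero_var},
        index=names,
    )
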