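"""Latent-variable discriminant modelling: PLS-DA, OPLS-DA, VIP, validation.

All models are fit natively with NIPALS-style algorithms:

* **PLS-DA** — NIPALS PLS2 regression of a centered class dummy matrix Y on
  the (Pareto-scaled) data matrix X.  Each component extracts an X-weight
  vector ``w`` maximizing covariance with the Y-scores, then deflates X and
  Y by the rank-one fit.
* **OPLS-DA** — for a binary (or one-contrast) response, variation in X
  orthogonal to y is removed component by component before a single
  predictive component is fit, splitting explained X-variation into a
  between-group share R2X(pred) and a within-group share R2X(ortho).
* **VIP** — variable importance in projection; the mean of squared VIPs is
  1 by construction, so VIP > 1 flags above-average contributors.
* **Validation** — venetian-blind k-fold Q² (default 7 folds) and label
  permutation testing (default n = 100): a model is accepted when the
  permutation R² regression line lies above the Q² line and the Q² line's
  intercept is negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassDesign",
    "LatentModel",
    "PermutationReport",
    "pareto_scale",
    "fit_plsda",
    "fit_oplsda",
    "inner_relation",
    "vip_scores",
    "q2_crossval",
    "permutation_test",
    "biplot_data",
]

NIPALS_TOL = 1e-10
# Convergence of the NIPALS inner loop is linear with rate lambda2/lambda1 of
# X'YY'X; label-permuted refits routinely produce near-degenerate component
# pairs whose rate approaches 1, where no iteration budget reaches 1e-10.
# At the cap a component that has contracted below the fallback tolerance is
# accepted (any vector of a near-degenerate eigenspace explains the same
# variance to that precision); only genuine non-contraction raises.
NIPALS_MAX_ITER = 5_000
NIPALS_FALLBACK_TOL = 1e-4


# ---------------------------------------------------------------------------
# scaling and design


def pareto_scale(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center each variable and divide by the square root of its SD.

    Pareto scaling is the chemometrics middle ground between no scaling
    (large peaks dominate) and unit-variance scaling (noise variables are
    inflated).  Sample SD (ddof=1) is used.  Zero-variance variables are
    centered and left undivided (divisor 1).

    Returns (scaled matrix, column means, column divisors).
    """
    if X.shape[0] < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    means = X.mean()
    sd = X.std(ddof=1)
    divisors = np.sqrt(sd)
    divisors[sd == 0] = 1.0
    return (X - means) / divisors, means, divisors


@dataclass
class ClassDesign:
    """Class labels and their dummy (one column per class, 0/1) response."""

    sample_ids: list[str]
    labels: list[str]
    classes: list[str] = field(init=False)
    Y: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels differ in length")
        self.classes = sorted(set(self.labels))
        dummy = np.zeros((len(self.labels), len(self.classes)))
        for i, lab in enumerate(self.labels):
            dummy[i, self.classes.index(lab)] = 1.0
        self.Y = pd.DataFrame(dummy, index=self.sample_ids, columns=self.classes)

    def contrast(self, positive_class: str) -> np.ndarray:
        """One-vs-rest response vector (1 for the class, 0 otherwise)."""
        if positive_class not in self.classes:
            raise ValueError(f"unknown class {positive_class!r}")
        return np.asarray([1.0 if lab == positive_class else 0.0 for lab in self.labels])


# ---------------------------------------------------------------------------
# models


@dataclass
class LatentModel:
    """A fitted PLS-DA or OPLS-DA model.

    Scores/loadings follow the usual chemometrics naming: T/P/W for the
    X-side scores, loadings and weights, C for Y-loadings, U for Y-scores.
    OPLS models additionally carry the y-orthogonal parts T_o/P_o/W_o and
    the predictive/orthogonal split of explained X-variation.
    """

    kind: str  # "PLS-DA" | "OPLS-DA"
    T: np.ndarray
    P: np.ndarray
    W: np.ndarray
    C: np.ndarray
    U: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    r2x: list[float]            # per predictive component
    r2y: list[float]            # cumulative
    ssy_explained: list[float]  # per-component explained Y sum of squares
    variable_ids: list[str]
    sample_ids: list[str]
    T_o: np.ndarray | None = None
    P_o: np.ndarray | None = None
    W_o: np.ndarray | None = None
    r2x_pred: float | None = None
    r2x_ortho: float | None = None
    q2: float | None = None

    @property
    def n_components(self) -> int:
        return self.T.shape[1]


def _sign_fix(w: np.ndarray) -> float:
    """Sign convention: the largest-magnitude weight entry is positive."""
    return 1.0 if w[np.argmax(np.abs(w))] >= 0 else -1.0


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index.astype(str)), list(X.columns.astype(str))
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[0])], [str(j) for j in range(X.shape[1])]


def _nipals_component(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One NIPALS PLS2 component on centered X, Y; returns (w, t, c, u, p)."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not u.any():
        u = Y[:, 0].copy()
    t_old = None
    last_change = np.inf
    for it in range(NIPALS_MAX_ITER):
        w = X.T @ u / (u @ u)
        norm_w = np.linalg.norm(w)
        if norm_w == 0:
            raise ArithmeticError("NIPALS produced a zero weight vector")
        w /= norm_w
        t = X @ w
        c = Y.T @ t / (t @ t)
        u = Y @ c / (c @ c)
        if t_old is not None:
            denom = np.linalg.norm(t)
            last_change = 0.0 if denom == 0 else np.linalg.norm(t - t_old) / denom
            if denom == 0 or last_change < NIPALS_TOL:
                break
        t_old = t
    else:
        if not (last_change < NIPALS_FALLBACK_TOL):
            raise ArithmeticError(
                f"NIPALS did not converge in {NIPALS_MAX_ITER} iterations "
                f"(last relative score change {last_change:.3e})"
            )
        logging.getLogger(__name__).debug(
            "NIPALS accepted a near-degenerate component at relative score "
            "change %.3e after %d iterations",
            last_change,
            NIPALS_MAX_ITER,
        )
    s = _sign_fix(w)
    w, t, c, u = s * w, s * t, s * c, s * u
    p = X.T @ t / (t @ t)
    return w, t, c, u, p


def fit_plsda(X, design: ClassDesign, n_components: int = 2) -> LatentModel:
    """NIPALS PLS2 discriminant model of X against the class dummy matrix.

    X is expected Pareto-scaled (or otherwise preprocessed); X and Y are
    centered internally and the means stored for prediction.
    """
    Xm, sample_ids, variable_ids = _as_matrix(X)
    Y = design.Y.to_numpy(dtype=float)
    if Y.shape[1] < 2 and np.unique(design.labels).size < 2:
        raise ValueError("degenerate class design: need at least 2 classes")
    if Xm.shape[0] != Y.shape[0]:
        raise ValueError("X and class design have different sample counts")
    max_rank = min(Xm.shape[0] - 1, Xm.shape[1])
    if not (1 <= n_components <= max_rank):
        raise ValueError(f"n_components must be in [1, {max_rank}]")

    x_mean = Xm.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = Xm - x_mean
    Yc = Y - y_mean
    ssx_tot = float(np.sum(Xc**2))
    ssy_tot = float(np.sum(Yc**2))
    if ssx_tot == 0:
        raise ValueError("X has no variation")

    T, P, W, C, U = [], [], [], [], []
    r2x, r2y, ssy_explained = [], [], []
    Xr, Yr = Xc.copy(), Yc.copy()
    for _ in range(n_components):
        w, t, c, u, p = _nipals_component(Xr, Yr)
        T.append(t)
        P.append(p)
        W.append(w)
        C.append(c)
        U.append(u)
        r2x.append(float(np.sum(np.outer(t, p) ** 2)) / ssx_tot)
        ssy_before = float(np.sum(Yr**2))
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, c)
        ssy_explained.append(ssy_before - float(np.sum(Yr**2)))
        r2y.append(1.0 - float(np.sum(Yr**2)) / ssy_tot)

    return LatentModel(
        kind="PLS-DA",
        T=np.column_stack(T),
        P=np.column_stack(P),
        W=np.column_stack(W),
        C=np.column_stack(C),
        U=np.column_stack(U),
        x_mean=x_mean,
        y_mean=y_mean,
        r2x=r2x,
        r2y=r2y,
        ssy_explained=ssy_explained,
        variable_ids=variable_ids,
        sample_ids=sample_ids,
    )


def pls_coefficients(model: LatentModel) -> np.ndarray:
    """Regression coefficients B with Y_hat = (X - x_mean) @ B + y_mean."""
    PW = model.P.T @ model.W
    return model.W @ np.linalg.solve(PW, model.C.T)


def predict(model: LatentModel, X) -> np.ndarray:
    Xm, _, _ = _as_matrix(X)
    return (Xm - model.x_mean) @ pls_coefficients(model) + model.y_mean


def fit_oplsda(X, y, n_ortho: int = 1) -> LatentModel:
    """O-PLS discriminant model for a binary / one-contrast response.

    Iteratively removes from X the variation orthogonal to y (Trygg-Wold
    style: the orthogonal weight is the part of the loading p not along the
    predictive weight w), then fits a single predictive component.  For a
    multiclass design, form a one-vs-rest contrast first (``ClassDesign.contrast``).
    """
    Xm, sample_ids, variable_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != Xm.shape[0]:
        raise ValueError("X and y have different sample counts")
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("response is constant")
    if uniq.size > 2:
        raise ValueError(
            "OPLS-DA requires a binary or one-contrast response; "
            "encode a multiclass design as one-vs-rest first"
        )
    if n_ortho < 1:
        raise ValueError("n_ortho must be >= 1")

    x_mean = Xm.mean(axis=0)
    y_mean = float(y.mean())
    Xr = Xm - x_mean
    yc = y - y_mean
    ssx_tot = float(np.sum(Xr**2))

    w = Xr.T @ yc / (yc @ yc)
    w /= np.linalg.norm(w)
    T_o, P_o, W_o = [], [], []
    ssx_ortho = 0.0
    for _ in range(n_ortho):
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm_wo = np.linalg.norm(w_o)
        if norm_wo < 1e-12:
            break  # no y-orthogonal structure left
        w_o /= norm_wo
        s = _sign_fix(w_o)
        w_o *= s
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        ssx_ortho += float(np.sum(np.outer(t_o, p_o) ** 2))
        T_o.append(t_o)
        P_o.append(p_o)
        W_o.append(w_o)

    # predictive component on the filtered matrix
    s = _sign_fix(w)
    w = s * w
    t = Xr @ w
    p = Xr.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    u = yc * c / (c * c) if c != 0 else yc.copy()
    ssx_pred = float(np.sum(np.outer(t, p) ** 2))
    ss_res = float(np.sum((yc - t * c) ** 2))
    ssy_tot = float(np.sum(yc**2))

    def col(v):
        return v.reshape(-1, 1)

    return LatentModel(
        kind="OPLS-DA",
        T=col(t),
        P=col(p),
        W=col(w),
        C=np.array([[c]]),
        U=col(u),
        x_mean=x_mean,
        y_mean=np.array([y_mean]),
        r2x=[ssx_pred / ssx_tot],
        r2y=[1.0 - ss_res / ssy_tot],
        ssy_explained=[ssy_tot - ss_res],
        variable_ids=variable_ids,
        sample_ids=sample_ids,
        T_o=np.column_stack(T_o) if T_o else np.zeros((Xm.shape[0], 0)),
        P_o=np.column_stack(P_o) if P_o else np.zeros((Xm.shape[1], 0)),
        W_o=np.column_stack(W_o) if W_o else np.zeros((Xm.shape[1], 0)),
        r2x_pred=ssx_pred / ssx_tot,
        r2x_ortho=ssx_ortho / ssx_tot,
    )


# ---------------------------------------------------------------------------
# diagnostics


def inner_relation(model: LatentModel) -> dict[str, object]:
    """OLS of the first Y-scores u1 on the first X-scores t1.

    The inner relation visualizes how well the X-side projection tracks the
    class structure; its R-squared (squared Pearson correlation) is the
    goodness-of-fit of the latent regression.
    """
    t1 = model.T[:, 0]
    u1 = model.U[:, 0]
    if np.allclose(t1, t1[0]):
        raise ValueError("t1 is constant; inner relation undefined")
    slope, intercept = np.polyfit(t1, u1, 1)
    if np.allclose(u1, u1[0]):
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(t1, u1)[0, 1] ** 2)
    return {"t1": t1, "u1": u1, "slope": float(slope), "intercept": float(intercept), "r2": r2}


def vip_scores(model: LatentModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a[(w_ja / ||w_a||)^2 * SSY_a] / sum_a SSY_a )
    with p the number of variables and SSY_a the Y sum of squares explained
    by component a.  The mean of squared VIPs is exactly 1.
    """
    ssy = np.asarray(model.ssy_explained, dtype=float)
    if ssy.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    W = model.W
    wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    p = W.shape[0]
    vip = np.sqrt(p * (wn2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.variable_ids, name="VIP")


def _venetian_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Deterministic venetian-blind fold assignment after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[order] = np.arange(n) % folds
    return fold


def q2_crossval(
    X,
    Y,
    n_components: int = 2,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Cross-validated predictive ability Q² = 1 - PRESS/SS.

    Venetian-blind fold assignment (samples dealt into ``folds`` folds after
    a seeded shuffle); each fold is predicted by a PLS model refit on the
    remaining samples.  SS is the total sum of squares of the centered Y.
    Every class must remain represented in every training fold.
    """
    Xm, _, _ = _as_matrix(X)
    Ym = np.asarray(Y, dtype=float)
    if Ym.ndim == 1:
        Ym = Ym.reshape(-1, 1)
    n = Xm.shape[0]
    if folds > n:
        raise ValueError("more folds than samples")
    fold = _venetian_folds(n, folds, seed)
    classes = Ym.argmax(axis=1) if Ym.shape[1] > 1 else (Ym[:, 0] > Ym[:, 0].mean())
    press = 0.0
    for k in range(folds):
        train = fold != k
        test = ~train
        if not test.any():
            continue
        if np.unique(classes[train]).size != np.unique(classes).size:
            raise ValueError(
                f"training fold {k} is missing a class; use fewer folds"
            )
        design = _ArrayDesign(Ym[train])
        sub = fit_plsda(Xm[train], design, n_components=min(n_components, train.sum() - 1, Xm.shape[1]))
        pred = predict(sub, Xm[test])
        press += float(np.sum((Ym[test] - pred) ** 2))
    ss = float(np.sum((Ym - Ym.mean(axis=0)) ** 2))
    return 1.0 - press / ss


class _ArrayDesign:
    """Adapter presenting a numeric response matrix as a ClassDesign."""

    def __init__(self, Y: np.ndarray):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y.reshape(-1, 1)
        self.Y = pd.DataFrame(Y)
        self.labels = [str(i) for i in Y.argmax(axis=1)] if Y.shape[1] > 1 else [
            str(int(v > Y[:, 0].mean())) for v in Y[:, 0]
        ]
        self.sample_ids = [str(i) for i in range(Y.shape[0])]
        self.classes = sorted(set(self.labels))


@dataclass
class PermutationReport:
    """Label-permutation validation summary.

    ``correlations``/``r2``/``q2`` include the original model as the final
    entry (correlation 1).  The intercepts come from OLS lines of R² and Q²
    against the absolute correlation between permuted and original class
    assignments; a valid, non-overfitted model has its R² line above the Q²
    line, a negative Q² intercept, and an original Q² that no permuted
    model reaches (without the last condition a pure-noise model — whose
    permuted Q² values are all equally poor — would count as valid).
    """

    n_permutations: int
    correlations: np.ndarray
    r2: np.ndarray
    q2: np.ndarray
    r2_intercept: float
    q2_intercept: float
    valid: bool


def permutation_test(
    X,
    design: ClassDesign,
    n: int = 100,
    seed: int = 0,
    n_components: int = 2,
    folds: int = 7,
) -> PermutationReport:
    """Assess overfitting by refitting under permuted class labels."""
    if n < 10:
        raise ValueError("need at least 10 permutations for a stable intercept")
    Xm, _, _ = _as_matrix(X)
    Y = design.Y.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=0)
    denom = float(np.sum(Yc**2))

    def fit_metrics(Yp: np.ndarray) -> tuple[float, float]:
        d = _ArrayDesign(Yp)
        m = fit_plsda(Xm, d, n_components=n_components)
        q2 = q2_crossval(Xm, Yp, n_components=n_components, folds=folds, seed=seed)
        return m.r2y[-1], q2

    rng = np.random.default_rng(seed)
    cors, r2s, q2s = [], [], []
    for _ in range(n):
        perm = rng.permutation(Xm.shape[0])
        Yp = Y[perm]
        Ypc = Yp - Yp.mean(axis=0)
        cor = abs(float(np.sum(Ypc * Yc)) / denom)
        r2, q2 = fit_metrics(Yp)
        cors.append(cor)
        r2s.append(r2)
        q2s.append(q2)
    r2_orig, q2_orig = fit_metrics(Y)
    cors.append(1.0)
    r2s.append(r2_orig)
    q2s.append(q2_orig)

    cors_a = np.asarray(cors)
    r2_a = np.asarray(r2s)
    q2_a = np.asarray(q2s)
    r2_line = np.polyfit(cors_a, r2_a, 1)
    q2_line = np.polyfit(cors_a, q2_a, 1)
    r2_icpt = float(r2_line[1])
    q2_icpt = float(q2_line[1])
    return PermutationReport(
        n_permutations=n,
        correlations=cors_a,
        r2=r2_a,
        q2=q2_a,
        r2_intercept=r2_icpt,
        q2_intercept=q2_icpt,
        valid=(r2_icpt > q2_icpt) and (q2_icpt < 0) and (q2_orig > float(np.max(q2_a[:-1]))),
    )


def biplot_data(model: LatentModel, block_of: pd.Series | None = None) -> pd.DataFrame:
    """Joint scores/loadings coordinates on a common [-1, 1] range.

    Sample scores (t1, t2) and variable loadings (p1, p2) are each
    max-abs-normalized per block of the biplot so both clouds share the
    plotting range.  ``block_of`` (variable id -> block tag) is carried
    through for symbol coding of m/z features vs delta bins.
    """
    if model.n_components < 2:
        raise ValueError("biplot needs at least 2 components")

    def norm(M: np.ndarray) -> np.ndarray:
        m = np.max(np.abs(M))
        return M / m if m > 0 else M

    scores = norm(model.T[:, :2])
    loadings = norm(model.P[:, :2])
    rows = []
    for i, sid in enumerate(model.sample_ids):
        rows.append({"id": sid, "kind": "sample", "block": "", "x": scores[i, 0], "y": scores[i, 1]})
    for j, vid in enumerate(model.variable_ids):
        blk = "" if block_of is None else str(block_of.get(vid, ""))
        rows.append({"id": vid, "kind": "variable", "block": blk, "x": loadings[j, 0], "y": loadings[j, 1]})
    return pd.DataFrame(rows)
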