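"""PLS-DA and OPLS-DA with VIP scores, Q2 cross-validation and permutation
testing.

Classes are dummy-coded one column per class (centered); latent variables
are extracted by NIPALS.  OPLS-DA (two classes only) first strips
class-orthogonal structured variation from X, then fits a single
predictive component on the filtered matrix, so the predictive scores
carry all the between-class separation.

Model quality is summarised by R2Y (fit), Q2Y (5-fold cross-validated
prediction of the dummy matrix), a label-permutation test on Q2Y/R2Y, and
a cross-validated-residual ANOVA in its simple F form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "PlsModel",
    "OplsModel",
    "ValidationResult",
    "dummy_code",
    "plsda_fit",
    "plsda_predict",
    "vip_scores",
    "q2_crossval",
    "oplsda_fit",
    "permutation_test",
    "cv_anova",
    "stratified_folds",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


def dummy_code(y: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """One indicator column per class (uncentered 0/1)."""
    y = np.asarray(y)
    labels = [str(g) for g in np.unique(y)]
    Y = np.zeros((y.size, len(labels)))
    for gi, g in enumerate(labels):
        Y[np.asarray(y).astype(str) == g, gi] = 1.0
    return Y, labels


@dataclass
class PlsModel:
    labels: list[str]
    n_components: int
    weights: np.ndarray = field(repr=False)      # (p, A) x-weights, unit norm
    scores: np.ndarray = field(repr=False)       # (n, A) x-scores
    x_loadings: np.ndarray = field(repr=False)   # (p, A)
    y_loadings: np.ndarray = field(repr=False)   # (q, A)
    y_mean: np.ndarray = field(repr=False)
    coef: np.ndarray = field(repr=False)         # (p, q) regression matrix
    r2y: float = 0.0
    ssy_per_component: np.ndarray | None = None


def plsda_fit(X: np.ndarray, y: np.ndarray, n_comp: int) -> PlsModel:
    """NIPALS PLS2 on autoscaled X against centered dummy-coded classes."""
    X = np.array(X, dtype=float)
    n, p = X.shape
    if n_comp >= min(n, p + 1):
        raise ValueError(f"n_comp={n_comp} too large for a {n}x{p} matrix")
    Y_raw, labels = dummy_code(y)
    y_mean = Y_raw.mean(axis=0)
    Y = Y_raw - y_mean
    ss_y0 = float((Y**2).sum())
    Xd, Yd = X.copy(), Y.copy()
    W, T, P, Q, ssy = [], [], [], [], []
    for _ in range(n_comp):
        u = Yd[:, int(np.argmax((Yd**2).sum(axis=0)))]
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw < _NIPALS_TOL:
                raise ValueError("ran out of X variance: reduce n_comp")
            w /= nw
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            u = Yd @ q / (q @ q) if (q @ q) > 0 else t
            if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        p_load = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q)
        W.append(w); T.append(t); P.append(p_load); Q.append(q)
        ssy.append(float((t @ t) * (q @ q)))
    W, T = np.column_stack(W), np.column_stack(T)
    P, Q = np.column_stack(P), np.column_stack(Q)
    r2y = 1.0 - float((Yd**2).sum()) / ss_y0 if ss_y0 > 0 else 0.0
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return PlsModel(labels=labels, n_components=n_comp, weights=W, scores=T,
                    x_loadings=P, y_loadings=Q, y_mean=y_mean, coef=coef,
                    r2y=r2y, ssy_per_component=np.asarray(ssy))


def plsda_predict(m: PlsModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dummy estimates and argmax class assignment."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Yhat = X @ m.coef + m.y_mean
    pred = np.array([m.labels[i] for i in Yhat.argmax(axis=1)], dtype=object)
    return Yhat, pred


def vip_scores(m: PlsModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a).

    Since each weight vector has unit norm and the squared normalized
    weights sum to one per component, mean(VIP^2) = 1 identically.
    """
    W = m.weights
    ssy = m.ssy_per_component
    p = W.shape[0]
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    denom = ssy.sum()
    if denom <= 0:
        return np.ones(p)
    return np.sqrt(p * (wn2 @ ssy) / denom)


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (list of index arrays)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    start = 0
    for g in np.unique(y):
        idx = np.flatnonzero(y == g)
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(start + j) % n_folds].append(int(i))
        start += idx.size
    return [np.array(sorted(f), dtype=int) for f in folds]


def _autoscale_pair(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def q2_crossval(X: np.ndarray, y: np.ndarray, n_comp: int, folds: int = 5,
                seed: int = 0, n_orth: int | None = None) -> float:
    """Q2Y = 1 - PRESS/SS over held-out dummy predictions.

    Full refit per fold, including the autoscaler, so held-out samples
    never touch any fitted parameter.  ``X`` is the preprocessed but
    unscaled matrix.  With ``n_orth`` set, an OPLS model (two classes) is
    cross-validated instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Y_all, labels = dummy_code(y)
    fold_idx = stratified_folds(y, folds, seed)
    press = 0.0
    ss = 0.0
    for te in fold_idx:
        if te.size == 0:
            continue
        tr = np.setdiff1d(np.arange(y.size), te)
        if len(np.unique(y[tr])) < len(labels):
            raise ValueError("a cross-validation fold lost a whole class")
        Xtr, Xte = _autoscale_pair(X[tr], X[te])
        if n_orth is None:
            m = plsda_fit(Xtr, y[tr], n_comp)
            Yhat = Xte @ m.coef + m.y_mean
            y_mean = m.y_mean
            Ytr_mean_cols = Y_all[te] - y_mean
            press += float(((Y_all[te] - Yhat) ** 2).sum())
            ss += float((Ytr_mean_cols**2).sum())
        else:
            m = oplsda_fit(Xtr, y[tr], n_orth=n_orth)
            yhat = opls_predict_response(m, Xte)
            ytrue = np.where(np.asarray(y[te]).astype(str) == m.labels[1], 1.0, -1.0)
            press += float(((ytrue - yhat) ** 2).sum())
            ss += float(((ytrue - m.response_mean) ** 2).sum())
    return 1.0 - press / ss if ss > 0 else float("nan")


@dataclass
class OplsModel:
    labels: list[str]                       # [negative, positive] in label order
    w_pred: np.ndarray = field(repr=False)  # (p,) predictive weight, unit norm
    t_pred: np.ndarray = field(repr=False)  # (n,) predictive scores
    p_pred: np.ndarray = field(repr=False)
    w_orth: np.ndarray = field(repr=False)  # (p, n_orth)
    t_orth: np.ndarray = field(repr=False)  # (n, n_orth)
    p_orth: np.ndarray = field(repr=False)
    q_pred: float = 0.0                     # y-loading of the predictive comp
    response_mean: float = 0.0
    r2y: float = 0.0


def oplsda_fit(X: np.ndarray, y: np.ndarray, n_orth: int = 1) -> OplsModel:
    """O-PLS split of X into class-predictive and class-orthogonal parts.

    Two classes only (coded -1/+1 by sorted label order).  Each orthogonal
    component is built from the part of the X-loading that is orthogonal
    to the predictive weight; X is deflated by it before the final single
    predictive component is extracted.  With no structured orthogonal
    variation the model reduces to one-component PLS.
    """
    X = np.array(X, dtype=float)
    y = np.asarray(y)
    labels = [str(g) for g in np.unique(y)]
    if len(labels) != 2:
        raise ValueError("OPLS-DA is two-class; use plsda_fit for more classes")
    yv = np.where(y.astype(str) == labels[1], 1.0, -1.0)
    y_mean = float(yv.mean())
    yc = yv - y_mean
    ss_y0 = float(yc @ yc)
    w = X.T @ yc
    w /= np.linalg.norm(w)
    Xd = X.copy()
    Wo, To, Po = [], [], []
    for _ in range(n_orth):
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nw = np.linalg.norm(w_o)
        if nw < 1e-12:
            warnings.warn("no orthogonal variation left; fewer components kept",
                          stacklevel=2)
            break
        w_o /= nw
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        Wo.append(w_o); To.append(t_o); Po.append(p_o)
    t_pred = Xd @ w
    p_pred = Xd.T @ t_pred / (t_pred @ t_pred)
    q = float(yc @ t_pred / (t_pred @ t_pred))
    resid = yc - q * t_pred
    r2y = 1.0 - float(resid @ resid) / ss_y0 if ss_y0 > 0 else 0.0
    return OplsModel(
        labels=labels, w_pred=w, t_pred=t_pred, p_pred=p_pred, q_pred=q,
        w_orth=np.column_stack(Wo) if Wo else np.zeros((X.shape[1], 0)),
        t_orth=np.column_stack(To) if To else np.zeros((X.shape[0], 0)),
        p_orth=np.column_stack(Po) if Po else np.zeros((X.shape[1], 0)),
        response_mean=y_mean, r2y=r2y,
    )


def opls_predict_response(m: OplsModel, X: np.ndarray) -> np.ndarray:
    """Continuous -1/+1 response estimate for new (scaled) spectra."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xd = X.copy()
    for a in range(m.t_orth.shape[1]):
        t_o = Xd @ m.w_orth[:, a]
        Xd = Xd - np.outer(t_o, m.p_orth[:, a])
    t = Xd @ m.w_pred
    return m.q_pred * t + m.response_mean


def opls_vip(m: OplsModel) -> np.ndarray:
    """VIP of the single predictive component: sqrt(p) * |w_pred|-normalized."""
    w2 = (m.w_pred / np.linalg.norm(m.w_pred)) ** 2
    return np.sqrt(w2 * w2.size)


def top_bands(values: np.ndarray, wavenumbers: np.ndarray, n: int = 10,
              min_separation: float = 4.0) -> list[float]:
    """The ``n`` highest-scoring distinct bands of an importance spectrum.

    On a finely gridded spectrum, adjacent columns of one absorption band
    carry near-identical importance (VIP, selection weight, ...), so a raw
    top-``n`` of columns lists one band many times.  This picks score
    maxima greedily while suppressing all columns within
    ``min_separation`` cm^-1 (default: the nominal 4 cm^-1 optical
    resolution) of an already-reported band — one entry per band, the way
    important wavenumbers are quoted in vibrational spectroscopy.
    """
    values = np.asarray(values, dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    order = np.argsort(values)[::-1]
    picked: list[float] = []
    for j in order:
        nu = float(wavenumbers[j])
        if all(abs(nu - b) >= min_separation for b in picked):
            picked.append(nu)
        if len(picked) == n:
            break
    return picked


@dataclass
class ValidationResult:
    r2y: float
    q2y: float
    p_r2: float | None = None
    p_q2: float | None = None
    cv_anova_f: float | None = None
    cv_anova_p: float | None = None
    fold_seed: int = 0


def permutation_test(X: np.ndarray, y: np.ndarray, n_perm: int = 999,
                     seed: int = 0, n_comp: int = 1, n_orth: int | None = 1,
                     folds: int = 5) -> dict[str, float]:
    """Label-permutation null for R2Y and Q2Y.

    p = (1 + #{permuted statistic >= observed}) / (1 + n_perm); the primary
    statistic is Q2Y, with R2Y reported alongside.
    """
    if n_perm < 19:
        warnings.warn("fewer than 19 permutations gives poor p-value resolution",
                      stacklevel=2)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    def fit_stats(yy: np.ndarray, fold_seed: int) -> tuple[float, float]:
        Xs, _ = _autoscale_pair(X, X)
        if n_orth is None:
            r2 = plsda_fit(Xs, yy, n_comp).r2y
        else:
            r2 = oplsda_fit(Xs, yy, n_orth=n_orth).r2y
        q2 = q2_crossval(X, yy, n_comp, folds=folds, seed=fold_seed, n_orth=n_orth)
        return r2, q2

    r2_obs, q2_obs = fit_stats(y, int(rng.integers(2**31)))
    ge_r2 = ge_q2 = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        r2p, q2p = fit_stats(yp, int(rng.integers(2**31)))
        ge_r2 += r2p >= r2_obs
        ge_q2 += q2p >= q2_obs
    return {
        "r2y": r2_obs,
        "q2y": q2_obs,
        "p_r2": (1 + ge_r2) / (1 + n_perm),
        "p_q2": (1 + ge_q2) / (1 + n_perm),
    }


def cv_anova(press: float, ss_tot: float, n: int, n_param: int) -> tuple[float, float]:
    """Approximate F test on cross-validated residuals.

    F = [(SS_tot - PRESS)/d1] / [PRESS/d2] with d1 = n_param (number of
    latent variables) and d2 = n - n_param - 1.  When PRESS >= SS_tot the
    model predicts no better than the mean: F <= 0 is reported with p = 1.
    """
    if n_param < 1 or n - n_param - 1 < 1:
        raise ValueError("invalid degrees of freedom for CV-ANOVA")
    d1, d2 = n_param, n - n_param - 1
    if press <= 0:
        return float("inf"), 0.0
    F = ((ss_tot - press) / d1) / (press / d2)
    if F <= 0:
        return F, 1.0
    return F, float(f_dist.sf(F, d1, d2))
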