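"""SELECT stepwise-orthogonalization variable selection and LDA.

SELECT picks, one at a time, the variable with the largest class-separation
weight (Fisher between/within variance ratio), then projects every
remaining variable onto the orthogonal complement of the pick before the
next round.  Redundant neighbours of an already-picked band therefore lose
their weight and are never co-selected.  The number of retained variables
is bounded by the 3:1 training-samples-to-variables rule.

LDA assigns objects to the class with the smallest Mahalanobis distance
under the pooled within-class covariance with equal priors; canonical
variates (eigenvectors of W^-1 B) are exported for score plots.
Classification quality is reported for resubstitution, leave-one-out
cross-validation on the fixed selected subset, and an external test set.
A nested variant that re-runs selection inside each leave-one-out fold is
provided for honest validation of the whole selection+classification
procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .dataset import SpectraSet

__all__ = [
    "SelectionResult",
    "LdaModel",
    "ClassificationReport",
    "fisher_weight",
    "max_variables_rule",
    "select_decorrelate",
    "lda_fit",
    "lda_predict",
    "loo_crossval",
    "nested_loo_select_lda",
    "split_train_test",
]

#: Weight reported when a variable separates classes with zero within-class
#: variance (infinite Fisher ratio).
INFINITE_SEPARATION = 1e12

_ZERO_NORM_TOL = 1e-12


def fisher_weight(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-variable between/within class variance ratio.

    between_j = sum_g n_g (mean_gj - mean_j)^2 / (G - 1)
    within_j  = pooled within-class variance (n - G denominator)
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size < 2:
        raise ValueError("fisher_weight requires at least 2 classes")
    n, _ = X.shape
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within_ss = np.zeros(X.shape[1])
    for g in labels:
        block = X[y == g]
        if block.shape[0] < 2:
            raise ValueError(f"class {g!r} needs at least 2 samples")
        m = block.mean(axis=0)
        between += block.shape[0] * (m - grand) ** 2
        within_ss += ((block - m) ** 2).sum(axis=0)
    between /= labels.size - 1
    within = within_ss / (n - labels.size)
    out = np.zeros(X.shape[1])
    ok = within > 0
    out[ok] = between[ok] / within[ok]
    out[(~ok) & (between > 0)] = INFINITE_SEPARATION
    return out


def max_variables_rule(n_train: int) -> int:
    """3:1 rule: at most floor(n_train / 3) variables may be retained."""
    if n_train < 3:
        raise ValueError("need at least 3 training samples")
    return n_train // 3


@dataclass
class SelectionResult:
    selected: list[float]            # wavenumbers in pick order
    selected_idx: list[int]          # column indices in pick order
    weights: list[float]             # Fisher weight of each pick at its step
    deco_matrix: np.ndarray          # design matrix after all decorrelations
    k_max_rule: int

    def __post_init__(self) -> None:
        if len(set(self.selected_idx)) != len(self.selected_idx):
            raise ValueError("duplicate variables selected")
        if len(self.selected) > self.k_max_rule:
            raise ValueError("selection exceeds the 3:1 sample/variable bound")


def select_decorrelate(X: np.ndarray, y: np.ndarray, k: int,
                       wavenumbers: np.ndarray | None = None) -> SelectionResult:
    """Stepwise selection with orthogonalization of the remaining variables.

    Each round: compute Fisher weights on the current (decorrelated) matrix,
    pick the argmax (ties toward the lower column index), then remove the
    picked column's direction from every remaining column.  Stops early
    with a warning if the best remaining column has (numerically) zero
    norm.  ``X`` is expected autoscaled.
    """
    X = np.array(X, dtype=float)
    n = X.shape[0]
    k_max = max_variables_rule(n)
    if k > k_max:
        raise ValueError(f"k={k} exceeds the 3:1 rule bound {k_max} for n={n}")
    if wavenumbers is None:
        wavenumbers = np.arange(X.shape[1], dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)

    picked: list[int] = []
    weights: list[float] = []
    available = np.ones(X.shape[1], dtype=bool)
    for _ in range(k):
        norms = np.einsum("ij,ij->j", X, X)
        candidate = available & (norms > _ZERO_NORM_TOL)
        if not candidate.any():
            warnings.warn(
                f"selection stopped early with {len(picked)} of {k} variables "
                "(remaining columns have zero norm)", stacklevel=2)
            break
        w = fisher_weight(X, y)
        w[~candidate] = -np.inf
        j = int(np.argmax(w))  # first max = lowest column index on ties
        picked.append(j)
        weights.append(float(w[j]))
        available[j] = False
        # project all still-available columns onto the complement of column j
        v = X[:, j]
        coef = (X.T @ v) / (v @ v)
        coef[~available] = 0.0
        X -= np.outer(v, coef)
    return SelectionResult(
        selected=[float(wavenumbers[j]) for j in picked],
        selected_idx=picked,
        weights=weights,
        deco_matrix=X,
        k_max_rule=k_max,
    )


@dataclass
class LdaModel:
    labels: list[str]
    means: np.ndarray                 # (G, p) class means
    pooled_cov: np.ndarray            # (p, p)
    cov_inv: np.ndarray = field(repr=False)
    canonical: np.ndarray = field(repr=False)   # (p, G-1) variate basis
    priors: str = "equal"


def lda_fit(X: np.ndarray, y: np.ndarray) -> LdaModel:
    """Pooled-covariance LDA with equal class priors.

    A small ridge (1e-8 * trace/p) is added if the pooled covariance is not
    positive definite; the event is logged as a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = [str(g) for g in np.unique(y)]
    G, (n, p) = len(labels), X.shape
    if n <= G:
        raise ValueError("need more samples than classes")
    means = np.vstack([X[y == g].mean(axis=0) for g in labels])
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    grand = X.mean(axis=0)
    for gi, g in enumerate(labels):
        block = X[y == g] - means[gi]
        Sw += block.T @ block
        d = (means[gi] - grand)[:, None]
        Sb += (y == g).sum() * (d @ d.T)
    Sw /= n - G
    try:
        cho = scipy.linalg.cho_factor(Sw)
        cov_inv = scipy.linalg.cho_solve(cho, np.eye(p))
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        tr = np.trace(Sw)
        ridge = 1e-8 * tr / p if tr > 0 else 1e-10
        warnings.warn(f"pooled covariance singular; ridge {ridge:g} added",
                      stacklevel=2)
        Sw = Sw + ridge * np.eye(p)
        cov_inv = np.linalg.inv(Sw)
    # canonical variates: generalized eigenproblem Sb v = lambda Sw v
    n_cv = min(G - 1, p)
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
        canonical = evecs[:, ::-1][:, :n_cv]
    except scipy.linalg.LinAlgError:
        canonical = np.linalg.eigh(cov_inv @ Sb)[1][:, ::-1][:, :n_cv]
    return LdaModel(labels=labels, means=means, pooled_cov=Sw,
                    cov_inv=cov_inv, canonical=canonical)


def lda_predict(m: LdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each row to the class with minimal Mahalanobis distance.

    Ties go to the first class in label order.  Returns (labels, canonical
    scores).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d2 = np.empty((X.shape[0], len(m.labels)))
    for gi in range(len(m.labels)):
        diff = X - m.means[gi]
        d2[:, gi] = np.einsum("ij,jk,ik->i", diff, m.cov_inv, diff)
    pred = np.array([m.labels[i] for i in d2.argmin(axis=1)], dtype=object)
    return pred, X @ m.canonical


@dataclass
class ClassificationReport:
    """Per-class and total % correct for each validation stage.

    Stages mirror the reporting convention of discriminant-analysis result
    tables: "classification" (resubstitution), "prediction" (internal CV)
    and "external" (held-out test set).  Confusion matrix rows are true
    classes in label order.
    """

    labels: list[str]
    confusion: dict[str, np.ndarray] = field(default_factory=dict)

    def add_stage(self, stage: str, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        cm = np.zeros((len(self.labels), len(self.labels)), dtype=int)
        idx = {g: i for i, g in enumerate(self.labels)}
        for t, p in zip(y_true, y_pred):
            cm[idx[str(t)], idx[str(p)]] += 1
        self.confusion[stage] = cm

    def per_class_pct(self, stage: str) -> dict[str, float]:
        cm = self.confusion[stage]
        out = {}
        for i, g in enumerate(self.labels):
            n = cm[i].sum()
            out[g] = 100.0 * cm[i, i] / n if n else float("nan")
        return out

    def total_pct(self, stage: str) -> float:
        cm = self.confusion[stage]
        total = cm.sum()
        rate = 100.0 * np.trace(cm) / total if total else float("nan")
        # total rate == sample-weighted mean of the per-class rates
        per = self.per_class_pct(stage)
        weighted = sum(
            per[g] * cm[i].sum() for i, g in enumerate(self.labels) if cm[i].sum()
        ) / total
        assert abs(rate - weighted) < 1e-9
        return rate

    def to_frame(self):
        import pandas as pd

        stages = list(self.confusion)
        rows = []
        for g in self.labels:
            rows.append([g] + [self.per_class_pct(s)[g] for s in stages])
        rows.append(["Total rate"] + [self.total_pct(s) for s in stages])
        titles = {"classification": "Classification (%)", "prediction": "Prediction (%)",
                  "external": "External Prediction (%)"}
        return pd.DataFrame(
            rows, columns=["Group"] + [titles.get(s, s + " (%)") for s in stages])


def loo_crossval(X_sel: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ClassificationReport]:
    """Leave-one-out CV of LDA on a FIXED variable subset.

    Variable selection is not repeated inside the loop; when the subset was
    chosen on the full data this estimate is optimistically biased (see
    ``nested_loo_select_lda`` for the honest alternative).
    """
    X_sel = np.asarray(X_sel, dtype=float)
    y = np.asarray(y)
    labels = [str(g) for g in np.unique(y)]
    if X_sel.shape[0] < len(labels) + 1:
        raise ValueError("too few samples for leave-one-out")
    preds = np.empty(X_sel.shape[0], dtype=object)
    for i in range(X_sel.shape[0]):
        mask = np.ones(X_sel.shape[0], dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < len(labels):
            raise ValueError("leaving one sample out empties a class")
        m = lda_fit(X_sel[mask], y[mask])
        preds[i] = lda_predict(m, X_sel[i : i + 1])[0][0]
    report = ClassificationReport(labels=labels)
    report.add_stage("prediction", y, preds)
    return preds, report


def nested_loo_select_lda(X: np.ndarray, y: np.ndarray, k: int,
                          wavenumbers: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out CV with SELECT re-run on every training fold.

    Unlike the fixed-subset procedure, the held-out sample never influences
    which variables are picked, so under a null cohort the accuracy stays
    at chance.  Autoscaling is also refit per fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    preds = np.empty(X.shape[0], dtype=object)
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[mask] - mu) / sd
        xte = (X[i] - mu) / sd
        k_i = min(k, max_variables_rule(int(mask.sum())))
        sel = select_decorrelate(Xtr, y[mask], k_i, wavenumbers)
        m = lda_fit(Xtr[:, sel.selected_idx], y[mask])
        preds[i] = lda_predict(m, xte[sel.selected_idx][None, :])[0][0]
    return preds


def split_train_test(s: SpectraSet, per_class: dict[str, int],
                     seed: int) -> tuple[SpectraSet, SpectraSet]:
    """Stratified random withdrawal of an external test set."""
    rng = np.random.default_rng(seed)
    test_rows: list[int] = []
    for g in sorted(per_class):
        idx = s.group_indices(g)
        want = per_class[g]
        if want > idx.size:
            raise ValueError(
                f"requested {want} test samples from class {g!r} of size {idx.size}")
        test_rows.extend(rng.choice(idx, size=want, replace=False).tolist())
    test_rows = sorted(test_rows)
    train_rows = [i for i in range(s.n_samples) if i not in set(test_rows)]
    return s.take(np.array(train_rows, dtype=int)), s.take(np.array(test_rows, dtype=int))
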