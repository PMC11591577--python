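"""Soft Independent Modelling of Class Analogy (SIMCA).

Each class gets its own principal-component model (class-centered PCA);
a new object's residual distance from a class model is compared to the
class's pooled residual dispersion with an F test.  Classification is
"open" (an object may be accepted by several classes, or none) or
"forced" (always assigned to the nearest model in F/F_crit terms).

Per-variable diagnostics follow classical SIMCA usage:

* modelling power  MP_j = 1 - sd_resid_j / sd_raw_j  (near 1: variable is
  well captured by the class subspace);
* discriminant power DP_j = sqrt[(S^2_j(A->B) + S^2_j(B->A)) /
  (S^2_j(A->A) + S^2_j(B->B))], the ratio of cross-class to own-class
  residual dispersion (>> 1: variable separates the classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "ClassPcaModel",
    "simca_fit",
    "choose_n_components",
    "object_distance",
    "simca_classify",
    "modeling_power",
    "discriminant_power",
    "power_table",
    "SimcaReport",
    "simca_report",
]

#: Sentinel DP when the own-class residual dispersion is exactly zero.
DP_SENTINEL = 1e12


@dataclass
class ClassPcaModel:
    label: str
    mean: np.ndarray                 # class-local column means
    loadings: np.ndarray = field(repr=False)   # (p, A), orthonormal
    n_components: int = 0
    n_train: int = 0
    s0: float = 0.0                  # pooled residual sd
    resid_sd: np.ndarray | None = None   # per-variable residual sd

    @property
    def n_variables(self) -> int:
        return self.mean.size

    def f_crit(self, alpha: float) -> float:
        p, A, n = self.n_variables, self.n_components, self.n_train
        return float(f_dist.ppf(1 - alpha, p - A, (n - A - 1) * (p - A)))


def simca_fit(X_class: np.ndarray, A: int) -> ClassPcaModel:
    """Class-centered PCA model with A components.

    Residual conventions: per-variable residual sd uses an (n - A - 1)
    denominator; the pooled residual sd s0 additionally divides by the
    residual dimensionality (p - A).  With A = 0 the model collapses to
    the class centroid and s0 to the pooled variable sd about it.
    """
    X_class = np.asarray(X_class, dtype=float)
    n, p = X_class.shape
    if n <= A + 1:
        raise ValueError(f"class of {n} samples cannot support A={A} components")
    mean = X_class.mean(axis=0)
    Xc = X_class - mean
    rank = np.linalg.matrix_rank(Xc) if A > 0 else 0
    if A > 0 and A >= min(n - 1, p) + 1 or (A > 0 and A > rank):
        raise ValueError(f"A={A} exceeds the rank of the centered class block")
    if A > 0:
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = Vt[:A].T
        E = Xc - (Xc @ loadings) @ loadings.T
    else:
        loadings = np.zeros((p, 0))
        E = Xc
    resid_sd = np.sqrt((E**2).sum(axis=0) / (n - A - 1))
    s0 = float(np.sqrt((E**2).sum() / ((p - A) * (n - A - 1))))
    return ClassPcaModel(label="", mean=mean, loadings=loadings, n_components=A,
                         n_train=n, s0=s0, resid_sd=resid_sd)


def choose_n_components(X_class: np.ndarray, max_components: int = 3) -> int:
    """Pick A by the minimum leave-one-out PRESS, capped at ``max_components``."""
    X_class = np.asarray(X_class, dtype=float)
    n, p = X_class.shape
    a_max = min(max_components, n - 2, p - 1)
    if a_max < 0:
        raise ValueError("class too small for a PCA model")
    press = np.zeros(a_max + 1)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mu = X_class[mask].mean(axis=0)
        Xc = X_class[mask] - mu
        xc = X_class[i] - mu
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        press[0] += float(xc @ xc)
        for A in range(1, a_max + 1):
            P = Vt[:A].T
            e = xc - P @ (P.T @ xc)
            press[A] += float(e @ e)
    return int(np.argmin(press))


def object_distance(m: ClassPcaModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual distance s_i and variance ratio F_i of objects to a model.

    s_i = sqrt(sum_j e_ij^2 / (p - A));  F_i = s_i^2 / s0^2.
    Accepts a single spectrum or a matrix; returns arrays.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != m.n_variables:
        raise ValueError("object is not on the model's variable grid")
    Xc = X - m.mean
    E = Xc - (Xc @ m.loadings) @ m.loadings.T
    s = np.sqrt((E**2).sum(axis=1) / (m.n_variables - m.n_components))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(m.s0 > 0, s**2 / m.s0**2, np.where(s > 0, np.inf, 0.0))
    return s, F


def simca_classify(models: list[ClassPcaModel], X: np.ndarray,
                   alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Open and forced classification against a list of class models.

    Open: object accepted by class g iff F_i < F_crit at 1 - alpha (may be
    several classes or none).  Forced: argmin of F_i / F_crit, ties toward
    the first model in list order.
    """
    if not models:
        raise ValueError("need at least one class model")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ratios = np.empty((X.shape[0], len(models)))
    accepted = np.zeros((X.shape[0], len(models)), dtype=bool)
    for gi, m in enumerate(models):
        _, F = object_distance(m, X)
        crit = m.f_crit(alpha)
        accepted[:, gi] = F < crit
        ratios[:, gi] = F / crit
    forced = np.array([models[i].label for i in ratios.argmin(axis=1)], dtype=object)
    return accepted, forced


def modeling_power(m: ClassPcaModel, X_class: np.ndarray) -> np.ndarray:
    """MP_j = 1 - sd_resid_j / sd_raw_j, clipped to [0, 1].

    sd_raw is the class-centered sd (n-1 denominator).  Variables with zero
    raw sd are undefined and returned as NaN with a warning.
    """
    X_class = np.asarray(X_class, dtype=float)
    raw_sd = X_class.std(axis=0, ddof=1)
    out = np.full(raw_sd.size, np.nan)
    flat = raw_sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} variable(s) with zero raw sd: MP undefined",
                      stacklevel=2)
    # match the A = 0 collapse: resid df (n - A - 1) equals raw df (n - 1)
    ok = ~flat
    out[ok] = 1.0 - m.resid_sd[ok] / raw_sd[ok]
    return np.clip(out, 0.0, 1.0, out=out)


def _cross_resid_ms(m: ClassPcaModel, X: np.ndarray, own: bool) -> np.ndarray:
    """Per-variable residual mean square of a block projected onto a model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = X - m.mean
    E = Xc - (Xc @ m.loadings) @ m.loadings.T
    n = X.shape[0]
    df = (n - m.n_components - 1) if own else n
    return (E**2).sum(axis=0) / df


def discriminant_power(mA: ClassPcaModel, mB: ClassPcaModel,
                       XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
    """DP per variable from the four projection residual dispersions.

    Cross-class dispersions use an n denominator, own-class dispersions the
    fitted-model (n - A - 1) denominator.  DP near 1 means the variable does
    not discriminate; a zero own-class denominator yields a large sentinel.
    """
    s2_ab = _cross_resid_ms(mB, XA, own=False)   # class A objects on model B
    s2_ba = _cross_resid_ms(mA, XB, own=False)
    s2_aa = _cross_resid_ms(mA, XA, own=True)
    s2_bb = _cross_resid_ms(mB, XB, own=True)
    denom = s2_aa + s2_bb
    out = np.full(denom.size, DP_SENTINEL)
    ok = denom > 0
    if not ok.all():
        warnings.warn("zero own-class residual dispersion: DP sentinel reported",
                      stacklevel=2)
    out[ok] = np.sqrt((s2_ab[ok] + s2_ba[ok]) / denom[ok])
    return out


def power_table(models: dict[str, ClassPcaModel], blocks: dict[str, np.ndarray],
                wavenumbers: np.ndarray) -> pd.DataFrame:
    """Per-variable DP (first pair of classes) and MP per class.

    Rows are variables sorted by descending DP; columns: the wavenumber,
    "Discriminant Power", then one "Modeling Power <class>" per class.
    For more than two classes, DP is the maximum over class pairs.
    """
    labels = list(models)
    dps = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            dps.append(discriminant_power(models[a], models[b], blocks[a], blocks[b]))
    dp = np.max(dps, axis=0) if dps else np.zeros(len(wavenumbers))
    data = {"Spectra Variable": np.asarray(wavenumbers, dtype=float),
            "Discriminant Power": dp}
    for g in labels:
        data[f"Modeling Power {g}"] = modeling_power(models[g], blocks[g])
    df = pd.DataFrame(data)
    return df.sort_values("Discriminant Power", ascending=False).reset_index(drop=True)


@dataclass
class SimcaReport:
    """Class-model quality: sensitivity/specificity style percentages.

    ``rows`` maps class label -> dict with keys classification (resub own-
    class acceptance), internal_prediction (LOO own-class acceptance),
    external_prediction (test own-class acceptance), efficiency (geometric
    mean of open sensitivity and specificity), efficiency_forced (same but
    for forced assignment) and total_rate.
    """

    rows: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        cols = ["Classification (%)", "Internal Prediction (%)",
                "External Prediction (%)", "Efficiency (%)",
                "Efficiency Forced Model (%)", "Total Rate (%)"]
        keys = ["classification", "internal_prediction", "external_prediction",
                "efficiency", "efficiency_forced", "total_rate"]
        return pd.DataFrame(
            [[g] + [self.rows[g][k] for k in keys] for g in self.rows],
            columns=["Group"] + cols,
        )


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def simca_report(X_train: np.ndarray, y_train: np.ndarray,
                 X_test: np.ndarray | None, y_test: np.ndarray | None,
                 n_components: dict[str, int], alpha: float = 0.05) -> tuple[
                     SimcaReport, dict[str, ClassPcaModel]]:
    """Fit per-class models and assemble the class-modelling report.

    Internal prediction leaves each training object out, refits its own
    class model (component count fixed) and tests its acceptance.
    """
    y_train = np.asarray(y_train)
    labels = [str(g) for g in np.unique(y_train)]
    models: dict[str, ClassPcaModel] = {}
    for g in labels:
        block = X_train[y_train == g]
        m = simca_fit(block, n_components[g])
        m.label = g
        models[g] = m
    model_list = [models[g] for g in labels]
    acc_train, forced_train = simca_classify(model_list, X_train, alpha)
    rows: dict[str, dict[str, float]] = {}
    for gi, g in enumerate(labels):
        own = y_train == g
        other = ~own
        # resubstitution: own-class objects accepted by their model
        classification = _pct(int(acc_train[own, gi].sum()), int(own.sum()))
        # LOO internal prediction of own-class acceptance
        hits = 0
        block = X_train[own]
        for i in range(block.shape[0]):
            rest = np.delete(block, i, axis=0)
            mi = simca_fit(rest, min(models[g].n_components, rest.shape[0] - 2))
            mi.label = g
            _, Fi = object_distance(mi, block[i])
            hits += int(Fi[0] < mi.f_crit(alpha))
        internal = _pct(hits, block.shape[0])
        sens = acc_train[own, gi].mean() if own.any() else float("nan")
        spec = 1.0 - acc_train[other, gi].mean() if other.any() else float("nan")
        efficiency = 100.0 * float(np.sqrt(max(sens, 0) * max(spec, 0)))
        fsens = (forced_train[own] == g).mean() if own.any() else float("nan")
        fspec = (forced_train[other] != g).mean() if other.any() else float("nan")
        eff_forced = 100.0 * float(np.sqrt(max(fsens, 0) * max(fspec, 0)))
        if X_test is not None and y_test is not None and (np.asarray(y_test) == g).any():
            own_t = np.asarray(y_test) == g
            acc_test, _ = simca_classify(model_list, X_test[own_t], alpha)
            external = _pct(int(acc_test[:, gi].sum()), int(own_t.sum()))
        else:
            external = float("nan")
        vals = [classification, internal, external, efficiency, eff_forced]
        finite = [v for v in vals if np.isfinite(v)]
        rows[g] = {
            "classification": classification,
            "internal_prediction": internal,
            "external_prediction": external,
            "efficiency": efficiency,
            "efficiency_forced": eff_forced,
            "total_rate": float(np.mean(finite)) if finite else float("nan"),
        }
    return SimcaReport(rows=rows), models
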