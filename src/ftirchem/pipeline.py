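"""End-to-end orchestration of the two published discrimination tasks.

For each configured comparison (by default ALS at diagnosis vs healthy
controls, and the three-way ALS-T0 / ALS-T6 / other-neuromuscular task)
the pipeline: splits off a stratified external test set, runs the
preprocessing chain, fits the train-set autoscaler, produces a PCA
overview with advisory outlier flags, runs SELECT-LDA (resubstitution /
leave-one-out / external reports), SIMCA class models on the selected
variables, OPLS-DA (two classes) or PLS-DA (three classes) with Q2/R2Y,
permutation and CV-ANOVA validation, intersects the SELECT list with the
top-10 VIP list to find consensus bands, and evaluates each consensus
band as a single-wavenumber diagnostic with ROC/Youden statistics.

All randomness flows from one root seed through named substreams, so a
re-run with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2, f as f_dist

from .dataset import SpectraSet
from .preprocess import PreprocessConfig, apply_scaler, fit_scaler, preprocess
from .pls import (
    cv_anova, dummy_code, opls_vip, oplsda_fit, permutation_test, plsda_fit,
    plsda_predict, q2_crossval, top_bands, vip_scores,
)
from .roc import POSITIVE_IF_LOW, roc_curve
from .select_lda import (
    ClassificationReport, lda_fit, lda_predict, loo_crossval, select_decorrelate,
    split_train_test,
)
from .simca import choose_n_components, power_table, simca_report
from .synthetic import CohortConfig, default_cohort_config, generate_cohort

__all__ = [
    "ComparisonSpec",
    "PipelineConfig",
    "ReportBundle",
    "pca_overview",
    "consensus_bands",
    "run_pipeline",
    "default_pipeline_config",
]


@dataclass
class ComparisonSpec:
    name: str
    classes: list[str]
    test_per_class: dict[str, int]
    k_select: int = 10
    n_comp: int = 2                  # PLS-DA components (3+ classes)
    n_orth: int = 1                  # OPLS-DA orthogonal components (2 classes)
    folds: int = 5
    n_perm: int = 99
    alpha: float = 0.05
    roc_positive: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a comparison needs at least 2 classes")
        if not self.roc_positive:
            self.roc_positive = [self.classes[0]]


@dataclass
class PipelineConfig:
    cohort: CohortConfig
    preprocess: PreprocessConfig
    comparisons: list[ComparisonSpec]
    outdir: str = "ftirchem_out"
    seed: int = 0
    input_csv: str | None = None     # overrides simulation when set

    def to_dict(self) -> dict:
        # outdir is deliberately excluded: results must not depend on where
        # they are written, so neither may the manifest or config hash
        return {
            "cohort": self.cohort.to_dict(),
            "preprocess": asdict(self.preprocess),
            "comparisons": [asdict(c) for c in self.comparisons],
            "seed": self.seed,
            "input_csv": self.input_csv,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        from .synthetic import BandSpec, GroupEffect

        craw = dict(raw.get("cohort", {}))
        if "bands" in craw:
            craw["bands"] = [BandSpec(**b) for b in craw["bands"]]
        if "effects" in craw:
            craw["effects"] = [
                GroupEffect(e["group"], {float(k): v for k, v in e.get("deltas", {}).items()})
                for e in craw["effects"]
            ]
        for key in ("baseline_const", "baseline_slope", "scatter"):
            if key in craw:
                craw[key] = tuple(craw[key])
        cohort = CohortConfig(**craw)
        pp_raw = dict(raw.get("preprocess", {}))
        if "region" in pp_raw:
            pp_raw["region"] = tuple(pp_raw["region"])
        pp = PreprocessConfig(**pp_raw)
        comps = [ComparisonSpec(**c) for c in raw["comparisons"]]
        return cls(cohort=cohort, preprocess=pp, comparisons=comps,
                   outdir=raw.get("outdir", "ftirchem_out"),
                   seed=int(raw["seed"]), input_csv=raw.get("input_csv"))


def default_pipeline_config(seed: int = 0, outdir: str = "ftirchem_out",
                            n_perm: int = 99) -> PipelineConfig:
    """The two study comparisons on the default simulated cohort.

    External test sizes follow the published design: 5 + 5 held-out
    samples for the two-class task, 2 per class (6 total) for the
    three-class task; ten SELECT variables each.
    """
    return PipelineConfig(
        cohort=default_cohort_config(seed=seed),
        preprocess=PreprocessConfig(),
        comparisons=[
            ComparisonSpec(
                name="ALS_T0_vs_HC",
                classes=["ALS_T0", "HC"],
                test_per_class={"ALS_T0": 5, "HC": 5},
                k_select=10, n_orth=1, n_perm=n_perm,
                roc_positive=["ALS_T0"],
            ),
            ComparisonSpec(
                name="ALS_T0_vs_ALS_T6_vs_ON",
                classes=["ALS_T0", "ALS_T6", "ON"],
                test_per_class={"ALS_T0": 2, "ALS_T6": 2, "ON": 2},
                k_select=10, n_comp=2, n_perm=n_perm,
                roc_positive=["ALS_T0", "ALS_T6"],
            ),
        ],
        outdir=outdir,
        seed=seed,
    )


def _stage_seed(root: int, name: str) -> int:
    digest = hashlib.sha256(f"{root}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def pca_overview(X_scaled: np.ndarray, n_comp: int = 5,
                 limit: float = 0.99) -> dict:
    """PCA scores, explained variance and advisory outlier flags.

    Flags samples whose Hotelling T^2 or orthogonal residual Q exceeds the
    training limit (F-based for T^2, moment-matched scaled chi-square for
    Q).  ``limit`` is family-wise: it is Sidak-shared across the samples
    and the two statistics so that a clean cohort shows no flag with
    probability about ``limit``.  Flags are advisory: nothing is removed
    automatically.
    """
    X = np.asarray(X_scaled, dtype=float)
    n, p = X.shape
    A = min(n_comp, n - 1, p)
    q_point = limit ** (1.0 / (2 * n))   # per-sample, per-statistic quantile
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :A] * S[:A]
    lam = S[:A] ** 2 / (n - 1)
    total_var = (Xc**2).sum() / (n - 1)
    explained = 100.0 * lam / total_var
    t2 = (scores**2 / np.where(lam > 0, lam, 1.0)).sum(axis=1)
    t2_lim = A * (n - 1) / max(n - A, 1) * f_dist.ppf(q_point, A, max(n - A, 1))
    E = Xc - scores @ Vt[:A]
    q = (E**2).sum(axis=1)
    q_mean, q_var = q.mean(), q.var(ddof=1)
    if q_var > 0 and q_mean > 0:
        g, h = q_var / (2 * q_mean), 2 * q_mean**2 / q_var
        q_lim = g * chi2.ppf(q_point, h)
    else:
        q_lim = np.inf
    return {
        "scores": scores,
        "explained_pct": explained,
        "t2": t2, "t2_limit": float(t2_lim),
        "q": q, "q_limit": float(q_lim),
        "flagged": np.flatnonzero((t2 > t2_lim) | (q > q_lim)),
    }


def consensus_bands(lists: list[list[float]], tolerance: float = 0.0) -> pd.DataFrame:
    """Bands present in every list (within tolerance), with per-list ranks.

    The reported band value comes from the first list; ordering is by the
    best combined (summed) rank.  Ranks are 1-based positions.
    """
    if not lists or any(len(lst) == 0 for lst in lists):
        raise ValueError("all band lists must be non-empty")
    rows = []
    for r0, band in enumerate(lists[0]):
        ranks = [r0 + 1]
        for other in lists[1:]:
            hits = [i for i, b in enumerate(other) if abs(b - band) <= tolerance]
            if not hits:
                break
            ranks.append(min(hits) + 1)
        else:
            rows.append([band] + ranks + [sum(ranks)])
    cols = (["band"] + [f"rank_list{i + 1}" for i in range(len(lists))] + ["combined_rank"])
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("combined_rank", kind="stable").reset_index(drop=True)


@dataclass
class ReportBundle:
    manifest: dict
    comparisons: dict[str, dict]


def _run_comparison(cohort: SpectraSet, spec: ComparisonSpec,
                    pp_cfg: PreprocessConfig, root_seed: int) -> dict:
    sub = cohort.subset_groups(spec.classes)
    train_raw, test_raw = split_train_test(
        sub, spec.test_per_class, seed=_stage_seed(root_seed, f"split:{spec.name}"))
    train = preprocess(train_raw, pp_cfg)
    test = preprocess(test_raw, pp_cfg)
    scaler = fit_scaler(train)
    Xtr_s = apply_scaler(scaler, train)
    Xte_s = apply_scaler(scaler, test)
    Xtr, Xte = Xtr_s.absorbance, Xte_s.absorbance
    ytr, yte = train.groups, test.groups
    nus = train.grid.values

    out: dict = {"name": spec.name, "n_train": train.n_samples, "n_test": test.n_samples}

    pca = pca_overview(Xtr)
    out["pca"] = {
        "explained_pct": pca["explained_pct"].tolist(),
        "flagged_samples": [train.sample_ids[i] for i in pca["flagged"]],
    }
    out["pca_scores"] = pd.DataFrame(
        {"sample_id": train.sample_ids, "group": ytr,
         **{f"PC{i+1}": pca["scores"][:, i] for i in range(pca["scores"].shape[1])}})

    from .select_lda import max_variables_rule

    k_eff = min(spec.k_select, max_variables_rule(train.n_samples))
    sel = select_decorrelate(Xtr, ytr, k_eff, wavenumbers=nus)
    out["selection"] = sel
    out["k_effective"] = k_eff

    X_sel_tr = Xtr[:, sel.selected_idx]
    X_sel_te = Xte[:, sel.selected_idx]
    lda = lda_fit(X_sel_tr, ytr)
    report = ClassificationReport(labels=lda.labels)
    report.add_stage("classification", ytr, lda_predict(lda, X_sel_tr)[0])
    loo_pred, _ = loo_crossval(X_sel_tr, ytr)
    report.add_stage("prediction", ytr, loo_pred)
    report.add_stage("external", yte, lda_predict(lda, X_sel_te)[0])
    out["lda_report"] = report
    out["lda_scores"] = pd.DataFrame(
        {"sample_id": train.sample_ids, "group": ytr,
         **{f"CV{i+1}": s for i, s in enumerate(lda_predict(lda, X_sel_tr)[1].T)}})

    n_comp_by_class = {
        g: choose_n_components(X_sel_tr[ytr == g]) for g in lda.labels
    }
    sim_rep, sim_models = simca_report(X_sel_tr, ytr, X_sel_te, yte,
                                       n_comp_by_class, alpha=spec.alpha)
    out["simca_report"] = sim_rep
    out["simca_components"] = n_comp_by_class
    out["power_table"] = power_table(
        sim_models, {g: X_sel_tr[ytr == g] for g in lda.labels},
        np.array(sel.selected))

    # latent-variable model on the full preprocessed spectrum
    two_class = len(spec.classes) == 2
    fold_seed = _stage_seed(root_seed, f"folds:{spec.name}")
    if two_class:
        model = oplsda_fit(Xtr, ytr, n_orth=spec.n_orth)
        vip = opls_vip(model)
        q2 = q2_crossval(train.absorbance, ytr, 1, folds=spec.folds,
                         seed=fold_seed, n_orth=spec.n_orth)
        r2 = model.r2y
        n_param = 1 + spec.n_orth
        perm = permutation_test(train.absorbance, ytr, n_perm=spec.n_perm,
                                seed=_stage_seed(root_seed, f"perm:{spec.name}"),
                                n_orth=spec.n_orth, folds=spec.folds)
        out["opls_scores"] = pd.DataFrame(
            {"sample_id": train.sample_ids, "group": ytr,
             "t_pred": model.t_pred,
             **{f"t_orth{a+1}": model.t_orth[:, a]
                for a in range(model.t_orth.shape[1])}})
    else:
        model = plsda_fit(Xtr, ytr, spec.n_comp)
        vip = vip_scores(model)
        q2 = q2_crossval(train.absorbance, ytr, spec.n_comp, folds=spec.folds,
                         seed=fold_seed, n_orth=None)
        r2 = model.r2y
        n_param = spec.n_comp
        perm = permutation_test(train.absorbance, ytr, n_perm=spec.n_perm,
                                seed=_stage_seed(root_seed, f"perm:{spec.name}"),
                                n_comp=spec.n_comp, n_orth=None, folds=spec.folds)
        out["pls_scores"] = pd.DataFrame(
            {"sample_id": train.sample_ids, "group": ytr,
             **{f"t{a+1}": model.scores[:, a] for a in range(model.scores.shape[1])}})

    Y_dummy, _ = dummy_code(ytr)
    ss_tot = float(((Y_dummy - Y_dummy.mean(axis=0)) ** 2).sum())
    press = (1.0 - q2) * ss_tot
    f_stat, f_p = cv_anova(press, ss_tot, train.n_samples, n_param)
    out["validation"] = {
        "r2y": r2, "q2y": q2,
        "p_r2": perm["p_r2"], "p_q2": perm["p_q2"],
        "cv_anova_f": f_stat, "cv_anova_p": f_p,
        "n_perm": spec.n_perm,
    }

    # top-10 VIP as distinct band maxima (one entry per absorption band)
    vip_top10 = top_bands(vip, nus, n=10)
    vip_order = np.argsort(vip)[::-1]
    out["vip_table"] = pd.DataFrame(
        {"band": nus[vip_order[:50]], "vip": vip[vip_order[:50]]})
    out["vip_top10"] = vip_top10

    # bands found by BOTH strategies; matching within one 4 cm^-1
    # optical-resolution element treats neighbouring grid columns of a
    # single absorption band as the same finding
    cons = consensus_bands([sel.selected, vip_top10], tolerance=4.0)
    out["consensus"] = cons

    pos_mask = np.isin(ytr, spec.roc_positive)
    roc_results = {}
    for band in cons["band"]:
        j = train.grid.index_of(float(band))
        roc_results[float(band)] = roc_curve(Xtr[:, j], pos_mask,
                                             direction=None)
    out["roc"] = roc_results
    return out


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute every configured comparison and write all report tables."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.input_csv:
        cohort = SpectraSet.from_csv(cfg.input_csv)
    else:
        sim_cfg = cfg.cohort
        cohort = generate_cohort(sim_cfg)
    comparisons = {}
    for spec in cfg.comparisons:
        try:
            comparisons[spec.name] = _run_comparison(
                cohort, spec, cfg.preprocess, cfg.seed)
        except Exception as exc:  # re-raise with stage context
            raise RuntimeError(
                f"comparison {spec.name!r} failed under seed {cfg.seed}: {exc}"
            ) from exc
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples": cohort.n_samples,
        "comparisons": [c.name for c in cfg.comparisons],
    }
    bundle = ReportBundle(manifest=manifest, comparisons=comparisons)
    _write_bundle(bundle, cfg, outdir)
    return bundle


def _fmt(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, float_format="%.10g")


def _write_bundle(bundle: ReportBundle, cfg: PipelineConfig, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps({**bundle.manifest, "config": cfg.to_dict()},
                   indent=2, sort_keys=True, default=str))
    for name, res in bundle.comparisons.items():
        cdir = outdir / name
        cdir.mkdir(exist_ok=True)
        sel = res["selection"]
        (cdir / "selection.tsv").write_text(_fmt(pd.DataFrame(
            {"band": sel.selected, "weight": sel.weights})))
        (cdir / "lda_report.tsv").write_text(_fmt(res["lda_report"].to_frame()))
        (cdir / "simca_report.tsv").write_text(_fmt(res["simca_report"].to_frame()))
        (cdir / "power_table.tsv").write_text(_fmt(res["power_table"]))
        (cdir / "vip.tsv").write_text(_fmt(res["vip_table"]))
        (cdir / "consensus.tsv").write_text(_fmt(res["consensus"]))
        (cdir / "pca_scores.tsv").write_text(_fmt(res["pca_scores"]))
        score_key = "opls_scores" if "opls_scores" in res else "pls_scores"
        (cdir / "latent_scores.tsv").write_text(_fmt(res[score_key]))
        (cdir / "validation.json").write_text(
            json.dumps(res["validation"], indent=2, sort_keys=True))
        roc_summary = {}
        for band, r in res["roc"].items():
            roc_summary[str(band)] = {
                "auc": r.auc, "p_value": r.p_value, "direction": r.direction,
                "cut": r.youden_cut, "sensitivity": r.youden_sens,
                "specificity": r.youden_spec, "youden_j": r.youden_j,
            }
            (cdir / f"roc_{band:g}.tsv").write_text(_fmt(pd.DataFrame(
                {"cut": r.cuts, "sensitivity": r.sensitivity,
                 "specificity": r.specificity})))
        (cdir / "roc_summary.json").write_text(
            json.dumps(roc_summary, indent=2, sort_keys=True))
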