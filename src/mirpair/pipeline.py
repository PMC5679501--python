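"""End-to-end pipeline orchestration and reporting.

``run_pipeline`` executes load (or simulate) -> replicate aggregation ->
detection-limit masking -> QC filtering -> training/confirmation split ->
per-comparison pair screening, selection and evaluation (training,
confirmation, combined) -> stepwise classifier building with random-
forest validation -> optional sex-stratified re-analysis, and writes the
resulting tables (CSV), classifiers (JSON) and QC report to an output
directory.  All randomness derives from the configured seed, so a rerun
reproduces every output byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort, pairs as pair_mod, simulate as sim
from .classifier import (
    Classifier,
    ValidationReport,
    accept_classifier,
    bootstrap_rf_validate,
    classifier_metrics,
    stepwise_select,
)
from .cohort import CtMatrix
from .covariates import StratifiedRun, stratified_run
from .exceptions import ConfigurationError
from .pairs import MultiplicityPolicy, PairValues, pair_delta_ct

ND_GROUPS = ("AD", "PD", "FTD", "ALS")


@dataclasses.dataclass
class Comparison:
    case: str
    control: str
    pair_auc_threshold: float = 0.75
    classifier_auc_threshold: float = 0.9

    def __post_init__(self) -> None:
        for thr in (self.pair_auc_threshold, self.classifier_auc_threshold):
            if not 0.5 < thr <= 1.0:
                raise ConfigurationError("AUC thresholds must be in (0.5, 1]")

    @property
    def label(self) -> str:
        return f"{self.case}-vs-{self.control}"


def default_comparisons(groups: Sequence[str]) -> list[Comparison]:
    """Each disease vs control plus all disease-vs-disease contrasts.

    The heterogeneous FTD group uses the relaxed gates (pair AUC 0.70,
    classifier AUC 0.80).
    """
    nds = [g for g in ND_GROUPS if g in groups]
    comps = []
    for nd in nds:
        relaxed = nd == "FTD"
        comps.append(Comparison(
            nd, "control",
            pair_auc_threshold=0.70 if relaxed else 0.75,
            classifier_auc_threshold=0.80 if relaxed else 0.90,
        ))
    for i, a in enumerate(nds):
        for b in nds[i + 1:]:
            relaxed = "FTD" in (a, b)
            comps.append(Comparison(
                a, b,
                pair_auc_threshold=0.70 if relaxed else 0.75,
                classifier_auc_threshold=0.80 if relaxed else 0.90,
            ))
    return comps


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (files or synthetic input)."""

    ct_table: str | None = None
    metadata: str | None = None
    layout: str = "long"
    synthetic: sim.SyntheticConfig | None = None
    comparisons: list[Comparison] | None = None  # None -> defaults from groups
    alpha: float = 0.05
    rho_threshold: float = 0.8
    multiplicity_scope: str = "global"  # or "per_comparison"
    qc_mirnas: tuple[str, ...] = cohort.DEFAULT_QC_MIRNAS
    k_sd: float = 2.0
    detection_limit: float = 37.0
    min_complete_frac: float = 0.7
    max_pairs: int = 3
    min_gain: float = 0.005
    max_candidates: int = 10  # cap on stepwise candidate pool, by AUC
    rf_trees: int = 500
    strata: bool = False
    seed: int = 0
    outdir: str = "mirpair-out"

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "synthetic" in payload and payload["synthetic"] is not None:
            syn = payload["synthetic"]
            payload["synthetic"] = (
                syn if isinstance(syn, sim.SyntheticConfig)
                else sim.SyntheticConfig(**syn))
        if payload.get("comparisons"):
            payload["comparisons"] = [
                c if isinstance(c, Comparison) else Comparison(**c)
                for c in payload["comparisons"]
            ]
        if "qc_mirnas" in payload:
            payload["qc_mirnas"] = tuple(payload["qc_mirnas"])
        return cls(**payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(payload)

    def validate(self) -> None:
        if self.multiplicity_scope not in ("global", "per_comparison"):
            raise ConfigurationError(
                "multiplicity_scope must be 'global' or 'per_comparison'")
        if self.synthetic is None and (self.ct_table is None
                                       or self.metadata is None):
            raise ConfigurationError(
                "provide either a synthetic config or ct_table + metadata paths")


@dataclasses.dataclass
class ComparisonResult:
    comparison: Comparison
    pair_stats: pd.DataFrame  # all datasets + strata, tabulated
    classifier: Classifier | None
    accepted: bool
    validation: ValidationReport | None
    stratified: list[StratifiedRun] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class PipelineResult:
    matrix: CtMatrix
    meta: pd.DataFrame
    qc_report: cohort.QCReport
    policy: MultiplicityPolicy
    comparisons: list[ComparisonResult]
    outdir: Path
    log: list[str]


def _pair_features(m: CtMatrix, pair_list, sample_ids) -> pd.DataFrame:
    """Oriented scores (-delta Ct) of the given pairs for the given samples."""
    sub = m.subset(sample_ids)
    return pd.DataFrame(
        {p.label: -pair_delta_ct(sub, p).delta_ct for p in pair_list})


def _run_comparison(cfg: PipelineConfig, comp: Comparison, m: CtMatrix,
                    meta: pd.DataFrame, policy: MultiplicityPolicy,
                    log: list[str]) -> ComparisonResult:
    meta_idx = meta.set_index("sample_id")
    in_comp = meta_idx["group"].isin([comp.case, comp.control])
    ids = [s for s in m.sample_ids if s in meta_idx.index[in_comp]]
    sub_meta = meta_idx.loc[ids]

    frames = []

    def ids_of(tag: str) -> list[str]:
        if tag == "combined":
            return ids
        return [s for s in ids if sub_meta.loc[s, "split"] == tag]

    def labels_of(sample_ids) -> np.ndarray:
        return (sub_meta.loc[sample_ids, "group"] == comp.case).to_numpy()

    train_ids = ids_of("training")
    train_m = m.subset(train_ids)
    train_labels = labels_of(train_m.sample_ids)
    stats_train = pair_mod.screen_pairs(
        train_m, train_labels, "training", cfg.min_complete_frac)
    selected = pair_mod.select_pairs(
        stats_train, comp.pair_auc_threshold, policy)
    selected_labels = {s.pair.label for s in selected}
    for s in stats_train:
        s.selected = s.pair.label in selected_labels
    frames.append(pair_mod.stats_to_frame(
        stats_train, comparison=comp.label, stratum="all"))
    log.append(f"{comp.label}: {len(selected)} of {len(stats_train)} "
               f"analyzable pairs selected on training "
               f"(AUC >= {comp.pair_auc_threshold}, "
               f"p < {policy.p_threshold:.3g})")

    sel_pairs = [s.pair for s in selected]
    for tag in ("confirmation", "combined"):
        tag_ids = ids_of(tag)
        if sel_pairs and tag_ids:
            tag_m = m.subset(tag_ids)
            stats_tag = pair_mod.evaluate_pairs(
                tag_m, sel_pairs, labels_of(tag_m.sample_ids), tag)
            for s in stats_tag:
                s.selected = True
            frames.append(pair_mod.stats_to_frame(
                stats_tag, comparison=comp.label, stratum="all"))

    clf = None
    accepted = False
    validation = None
    if selected:
        candidates = selected[: cfg.max_candidates]
        feats_train = _pair_features(m, [s.pair for s in candidates], train_ids)
        complete = feats_train.notna().all(axis=1).to_numpy()
        y_train = train_labels[complete]
        if y_train.sum() >= 10 and (~y_train).sum() >= 10:
            clf = stepwise_select(
                candidates, feats_train.loc[complete], y_train,
                max_pairs=cfg.max_pairs, min_gain=cfg.min_gain,
                acceptance_threshold=comp.classifier_auc_threshold)
            for tag in ("confirmation", "combined"):
                tag_ids = ids_of(tag)
                feats = _pair_features(m, clf.pairs, tag_ids)
                keep = feats.notna().all(axis=1).to_numpy()
                y = labels_of(feats.index[keep])
                if y.any() and not y.all():
                    clf.metrics[tag] = classifier_metrics(
                        clf.fit, feats.loc[keep], y)
            if "combined" in clf.metrics:
                accepted = accept_classifier(
                    clf, "combined", comp.classifier_auc_threshold)
            feats_comb = _pair_features(m, clf.pairs, ids)
            keep = feats_comb.notna().all(axis=1).to_numpy()
            y_comb = labels_of(feats_comb.index[keep])
            if y_comb.sum() >= 10 and (~y_comb).sum() >= 10:
                validation = bootstrap_rf_validate(
                    feats_comb.loc[keep], y_comb, n_trees=cfg.rf_trees,
                    seed=cfg.seed)
            log.append(
                f"{comp.label}: classifier {[p.label for p in clf.pairs]} "
                f"combined AUC "
                f"{clf.metrics.get('combined', clf.metrics['training']).auc:.3f} "
                f"accepted={accepted}")
        else:
            log.append(f"{comp.label}: too few complete training samples for "
                       "a classifier")
    else:
        log.append(f"{comp.label}: no pairs passed the gates; classifier "
                   "section left empty")

    stratified: list[StratifiedRun] = []
    if cfg.strata:
        stratified = stratified_run(
            m, meta, comp.case, comp.control,
            auc_threshold=comp.pair_auc_threshold, policy=policy,
            max_pairs=cfg.max_pairs, min_gain=cfg.min_gain,
            classifier_threshold=comp.classifier_auc_threshold)
        for run in stratified:
            if run.stratum == "all":
                continue  # unstratified results already reported above
            frames.append(pair_mod.stats_to_frame(
                run.pair_stats, comparison=comp.label, stratum=run.stratum))

    pair_table = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame())
    return ComparisonResult(comp, pair_table, clf, accepted, validation,
                            stratified)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full discovery pipeline and write the report bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={cfg.seed}"]

    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        replicates, meta, truth = sim.simulate_cohort(syn)
        truth.to_json(outdir / "ground_truth.json")
        log.append(f"simulated cohort: {len(meta)} samples x "
                   f"{len(syn.mirnas)} miRNAs")
    else:
        replicates = cohort.load_ct_table(cfg.ct_table, cfg.layout)
        meta = cohort.load_metadata(cfg.metadata)
        log.append(f"loaded {cfg.ct_table}: {meta.shape[0]} samples")

    matrix = cohort.apply_detection_limit(
        cohort.aggregate_replicates(replicates, cfg.detection_limit))

    if all(q in matrix.ct.columns for q in cfg.qc_mirnas):
        matrix, qc_report = cohort.qc_filter_samples(
            matrix, cfg.qc_mirnas, cfg.k_sd)
        log.append(f"QC: removed {len(qc_report.failed_samples)} samples")
    else:
        warnings.warn("QC miRNAs absent from panel; QC filter skipped",
                      stacklevel=2)
        flags = pd.Series(True, index=matrix.ct.index)
        qc_report = cohort.QCReport(tuple(cfg.qc_mirnas), cfg.k_sd,
                                    pd.DataFrame(), flags, [])
    meta = meta[meta["sample_id"].isin(matrix.sample_ids)].reset_index(drop=True)

    if (meta["split"] == "unassigned").any():
        meta = cohort.split_train_confirm(meta, cfg.seed)
        log.append("assigned training/confirmation split")

    policy = pair_mod.effective_test_count(
        matrix, cfg.rho_threshold, cfg.alpha)
    log.append(
        f"multiplicity: {policy.n_pairs_effective} effective of "
        f"{policy.n_pairs_nominal} nominal pairs, p threshold "
        f"{policy.p_threshold:.3g}")

    comparisons = cfg.comparisons
    if comparisons is None:
        comparisons = default_comparisons(sorted(meta["group"].unique()))
    groups = set(meta["group"])
    for comp in comparisons:
        if comp.case not in groups or comp.control not in groups:
            raise ConfigurationError(
                f"comparison {comp.label} references an undefined group")

    results = []
    for comp in comparisons:
        comp_policy = policy
        if cfg.multiplicity_scope == "per_comparison":
            meta_idx = meta.set_index("sample_id")
            ids = [s for s in matrix.sample_ids
                   if meta_idx.loc[s, "group"] in (comp.case, comp.control)]
            comp_policy = pair_mod.effective_test_count(
                matrix.subset(ids), cfg.rho_threshold, cfg.alpha)
        results.append(_run_comparison(cfg, comp, matrix, meta, comp_policy,
                                       log))

    _write_bundle(outdir, matrix, meta, qc_report, policy, results, log)
    return PipelineResult(matrix, meta, qc_report, policy, results, outdir, log)


def _json_default(obj):
    """Coerce numpy scalars to plain Python for JSON output."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def _write_bundle(outdir: Path, matrix: CtMatrix, meta: pd.DataFrame,
                  qc_report: cohort.QCReport, policy: MultiplicityPolicy,
                  results: list[ComparisonResult], log: list[str]) -> None:
    matrix.to_csv(outdir / "ct_matrix.csv")
    meta.to_csv(outdir / "metadata.csv", index=False)
    qc_report.to_json(outdir / "qc_report.json")
    if not qc_report.batch_stats.empty:
        qc_report.batch_stats.to_csv(outdir / "qc_batch_stats.csv", index=False)

    tables = [r.pair_stats for r in results if not r.pair_stats.empty]
    pair_table = (pd.concat(tables, ignore_index=True) if tables
                  else pd.DataFrame())
    pair_table.to_csv(outdir / "pair_stats.csv", index=False)

    classifiers = {}
    for r in results:
        entry = {
            "accepted": r.accepted,
            "classifier": r.classifier.to_dict() if r.classifier else None,
            "validation": (dataclasses.asdict(r.validation)
                           if r.validation else None),
        }
        if r.stratified:
            entry["strata"] = {
                run.stratum: (run.classifier.to_dict()
                              if run.classifier else None)
                for run in r.stratified
            }
        classifiers[r.comparison.label] = entry
    payload = {
        "multiplicity": dataclasses.asdict(policy),
        "comparisons": classifiers,
    }
    (outdir / "classifiers.json").write_text(
        json.dumps(payload, indent=2, default=_json_default) + "\n")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_pair(values: PairValues, labels, path: str | Path | None = None,
              class_names: tuple[str, str] = ("control", "case")):
    """Box-and-whisker (log10 display ratio) plus ROC panel for one pair.

    Boxes span the 25th-75th percentiles with 10/90 whiskers and outlier
    points, matching the conventional presentation of ratio biomarkers.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(labels, dtype=bool)
    ratio = values.ratio.to_numpy(dtype=float)
    keep = np.isfinite(ratio)
    ratio, y = ratio[keep], y[keep]
    logratio = np.log10(ratio)

    fig, (ax_box, ax_roc) = plt.subplots(1, 2, figsize=(8, 3.6))
    ax_box.boxplot([logratio[~y], logratio[y]], whis=(10, 90),
                   tick_labels=list(class_names))
    ax_box.set_ylabel(r"$\log_{10}(2^{-\Delta Ct} \times 100)$")
    ax_box.set_title(values.pair.label)

    score = -values.delta_ct.to_numpy(dtype=float)[keep]
    order = np.argsort(-score, kind="stable")
    tps = np.concatenate([[0], np.cumsum(y[order])])
    fps = np.concatenate([[0], np.cumsum(~y[order])])
    tpr = tps / max(y.sum(), 1)
    fpr = fps / max((~y).sum(), 1)
    ax_roc.plot(fpr, tpr, drawstyle="steps-post")
    ax_roc.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax_roc.set_xlabel("1 - specificity")
    ax_roc.set_ylabel("sensitivity")
    ax_roc.set_title("ROC")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def report_figures(rundir: str | Path, top_n: int = 3) -> list[Path]:
    """Render figures for the top selected pairs of a completed run."""
    rundir = Path(rundir)
    matrix = CtMatrix(pd.read_csv(rundir / "ct_matrix.csv",
                                  index_col="sample_id"))
    meta = pd.read_csv(rundir / "metadata.csv").set_index("sample_id")
    stats = pd.read_csv(rundir / "pair_stats.csv")
    written = []
    if stats.empty:
        return written
    sel = stats[(stats["dataset_tag"] == "training") & stats["selected"]
                & (stats["stratum"] == "all")]
    for comp_label, block in sel.groupby("comparison"):
        case, control = comp_label.split("-vs-")
        ids = [s for s in matrix.sample_ids
               if meta.loc[s, "group"] in (case, control)]
        sub = matrix.subset(ids)
        y = (meta.loc[sub.sample_ids, "group"] == case).to_numpy()
        for _, row in block.nlargest(top_n, "auc").iterrows():
            num, den = row["pair"].split("/")
            values = pair_delta_ct(sub, pair_mod.Pair(num, den))
            safe = row["pair"].replace("/", "_vs_").replace("*", "star")
            out = rundir / f"pair_{comp_label}_{safe}.png"
            plot_pair(values, y, out, class_names=(control, case))
            written.append(out)
    return written
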