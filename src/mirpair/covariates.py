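"""Age/sex covariate models and sex-stratified re-analysis.

Cohort demographics are rarely perfectly balanced, so each candidate
ratio is probed with an additive OLS model (delta Ct ~ diagnosis + age or
sex) to check that discrimination is driven by diagnosis rather than a
covariate, ratios can be detrended against the control-group age slope,
and the whole pair-selection + classifier pipeline can be rerun within
all/male/female strata, including male-vs-female contrasts inside one
diagnosis group.
"""
from __future__ import annotations

import dataclasses
import warnings
import pandas as pd
import statsmodels.api as sm

from .classifier import Classifier, stepwise_select
from .cohort import CtMatrix
from .exceptions import ConfigurationError, InsufficientDataError
from .pairs import (
    MultiplicityPolicy,
    PairStat,
    PairValues,
    pair_delta_ct,
    screen_pairs,
    select_pairs,
)


@dataclasses.dataclass
class CovariateResult:
    pair: str
    group_coef: float
    group_p: float
    covariate: str
    covariate_coef: float
    covariate_p: float
    n: int


@dataclasses.dataclass
class StratifiedRun:
    stratum: str  # "all", "male" or "female"
    pair_stats: list[PairStat]
    selected: list[PairStat]
    classifier: Classifier | None
    n_case: int
    n_control: int


def _aligned_meta(values: PairValues, meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    df = pd.DataFrame({"delta_ct": values.delta_ct})
    return df.join(meta[["group", "sex", "age"]], how="left")


def covariate_regression(values: PairValues, meta: pd.DataFrame,
                         covariate: str = "age",
                         case_group: str | None = None) -> CovariateResult:
    """OLS of delta Ct on a diagnosis indicator plus one covariate.

    The model is additive (no interaction).  ``case_group`` names the
    diagnosis level coded 1; with exactly two groups present it may be
    omitted and the non-control (or lexicographically later) group is
    used.
    """
    if covariate not in ("age", "sex"):
        raise ConfigurationError("covariate must be 'age' or 'sex'")
    df = _aligned_meta(values, meta)
    df = df.dropna(subset=["delta_ct", "group", "sex"])
    if covariate == "age":
        df = df.dropna(subset=["age"])

    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise InsufficientDataError("exactly two diagnosis groups are required")
    if case_group is None:
        case_group = groups[1] if groups[0] == "control" else (
            [g for g in groups if g != "control"] or [groups[1]])[0]
    if case_group not in groups:
        raise ConfigurationError(f"case group '{case_group}' not present")
    if len(df) < 10:
        raise InsufficientDataError("need at least 10 complete cases")

    cov = df["age"].astype(float) if covariate == "age" else (
        (df["sex"] == "F").astype(float))
    if cov.nunique() < 2:
        raise ConfigurationError(f"covariate '{covariate}' is constant")

    x = pd.DataFrame(
        {"group": (df["group"] == case_group).astype(float), covariate: cov}
    )
    fit = sm.OLS(df["delta_ct"].astype(float), sm.add_constant(x)).fit()
    return CovariateResult(
        pair=values.pair.label,
        group_coef=float(fit.params["group"]),
        group_p=float(fit.pvalues["group"]),
        covariate=covariate,
        covariate_coef=float(fit.params[covariate]),
        covariate_p=float(fit.pvalues[covariate]),
        n=int(fit.nobs),
    )


def age_adjust(values: PairValues, meta: pd.DataFrame,
               reference_group: str = "control") -> PairValues:
    """Remove the reference-group linear age trend from every delta Ct.

    The slope is fitted by OLS on the reference group (centred at its mean
    age, so reference values keep their location), then
    ``slope * (age - mean_age_ref)`` is subtracted from all samples.
    Samples without an age cannot be adjusted and become missing, with a
    warning.  Idempotent: residuals of the reference group are exactly
    age-uncorrelated, so a refit gives slope 0.
    """
    df = _aligned_meta(values, meta)
    ref = df[(df["group"] == reference_group)
             & df["delta_ct"].notna() & df["age"].notna()]
    if len(ref) < 10:
        raise InsufficientDataError(
            f"need at least 10 aged reference samples in '{reference_group}'")
    age0 = float(ref["age"].mean())
    slope = float(
        sm.OLS(ref["delta_ct"].astype(float),
               sm.add_constant(ref["age"].astype(float) - age0)).fit().params.iloc[1]
    )
    missing_age = df["delta_ct"].notna() & df["age"].isna()
    if missing_age.any():
        warnings.warn(
            f"{int(missing_age.sum())} samples lack age and are excluded from "
            "age adjustment",
            stacklevel=2,
        )
    adjusted = df["delta_ct"] - slope * (df["age"] - age0)
    return PairValues(values.pair, adjusted.rename(values.delta_ct.name))


def _run_stratum(m: CtMatrix, meta: pd.DataFrame, case_group: str,
                 control_group: str, stratum: str, *,
                 auc_threshold: float, policy: MultiplicityPolicy,
                 max_pairs: int, min_gain: float,
                 classifier_threshold: float,
                 min_per_class: int = 5) -> StratifiedRun | None:
    idx = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    idx = idx.loc[[s for s in m.sample_ids if s in idx.index]]
    mask = idx["group"].isin([case_group, control_group])
    if stratum == "male":
        mask &= idx["sex"] == "M"
    elif stratum == "female":
        mask &= idx["sex"] == "F"
    sub_ids = idx.index[mask]
    sub_meta = idx.loc[sub_ids]
    n_case = int((sub_meta["group"] == case_group).sum())
    n_control = int((sub_meta["group"] == control_group).sum())
    if n_case < min_per_class or n_control < min_per_class:
        warnings.warn(
            f"stratum '{stratum}' skipped for {case_group} vs {control_group}: "
            f"{n_case} case / {n_control} control samples",
            stacklevel=3,
        )
        return None

    sub = m.subset(sub_ids)
    labels = (sub_meta.loc[sub.sample_ids, "group"] == case_group).to_numpy()
    stats_list = screen_pairs(sub, labels, dataset_tag=stratum)
    selected = select_pairs(stats_list, auc_threshold, policy)

    clf = None
    if selected:
        feats = pd.DataFrame(
            {s.pair.label: -pair_delta_ct(sub, s.pair).delta_ct for s in selected}
        )
        complete = feats.notna().all(axis=1).to_numpy()
        if labels[complete].sum() >= 5 and (~labels)[complete].sum() >= 5:
            clf = stepwise_select(selected, feats.loc[complete],
                                  labels[complete], max_pairs=max_pairs,
                                  min_gain=min_gain,
                                  acceptance_threshold=classifier_threshold)
    return StratifiedRun(stratum, stats_list, selected, clf, n_case, n_control)


def stratified_run(m: CtMatrix, meta: pd.DataFrame, case_group: str,
                   control_group: str = "control", *,
                   auc_threshold: float = 0.75,
                   policy: MultiplicityPolicy | None = None,
                   max_pairs: int = 3, min_gain: float = 0.005,
                   classifier_threshold: float = 0.9) -> list[StratifiedRun]:
    """Run the pair-selection + classifier pipeline in all/male/female strata.

    Each sex stratum compares cases with sex-matched controls; strata with
    fewer than 5 case or 5 control samples are skipped with a warning.
    """
    if policy is None:
        policy = MultiplicityPolicy.nominal(len(m.mirnas))
    runs = []
    for stratum in ("all", "male", "female"):
        run = _run_stratum(
            m, meta, case_group, control_group, stratum,
            auc_threshold=auc_threshold, policy=policy, max_pairs=max_pairs,
            min_gain=min_gain, classifier_threshold=classifier_threshold,
        )
        if run is not None:
            runs.append(run)
    return runs


def sex_contrast_within_group(m: CtMatrix, meta: pd.DataFrame,
                              group: str) -> list[PairStat]:
    """Male-vs-female pair statistics within one diagnosis group.

    Males are coded as the "case" class; orientation makes the resulting
    AUC symmetric under relabelling.
    """
    idx = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    idx = idx.loc[[s for s in m.sample_ids if s in idx.index]]
    sub_ids = idx.index[idx["group"] == group]
    sub_meta = idx.loc[sub_ids]
    n_m = int((sub_meta["sex"] == "M").sum())
    n_f = int((sub_meta["sex"] == "F").sum())
    if n_m < 5 or n_f < 5:
        raise InsufficientDataError(
            f"group '{group}' has {n_m} male / {n_f} female samples; "
            "need at least 5 of each")
    sub = m.subset(sub_ids)
    labels = (sub_meta.loc[sub.sample_ids, "sex"] == "M").to_numpy()
    return screen_pairs(sub, labels, dataset_tag=f"{group}:M-vs-F")
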