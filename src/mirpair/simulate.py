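"""Ground-truth case-control qRT-PCR cohort generator.

The generator draws per-sample latent Ct values from a correlated
Gaussian model on the Ct (log2 concentration) scale, applies additive
group, sex-restricted and age effects, adds triplicate reverse-
transcription noise, censors replicates above the detection limit
(masking only), and injects occasional QC-outlier preparations whose
every Ct is shifted.  A closed-form companion (:class:`GroundTruth`)
reports the theoretical AUC of any pair under the binormal
equal-variance delta-Ct model, so recovery of known effects can be
asserted at every pipeline stage.

The default configuration emulates the study conditions this package is
built around: a 37-miRNA brain-enriched panel measured in five groups of
50 (control, AD, PD, FTD, ALS) with Table-1-like demographics, an
8-fold (-3 Ct) muscle-miRNA increase in ALS, correlated miRNA blocks
that reduce the effective pair count to ~160, and a detection limit of
Ct 37.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import aggregate_replicates, apply_detection_limit, qc_filter_samples
from .exceptions import ConfigurationError
from .pairs import Pair, pairwise_mw_pvalues

#: variance of the median of 3 iid standard normals (replicate aggregation)
MEDIAN3_VAR = 0.449

DEFAULT_PANEL = (
    "let-7e", "miR-7", "miR-9", "miR-9*", "miR-16", "miR-27a", "miR-28",
    "miR-29a", "miR-31", "miR-99", "miR-99b", "miR-107", "miR-125b",
    "miR-127", "miR-128a", "miR-129-3p", "miR-132", "miR-134", "miR-137",
    "miR-146a", "miR-148b", "miR-155", "miR-181a", "miR-204", "miR-206",
    "miR-323-3p", "miR-335", "miR-338-3p", "miR-370", "miR-382", "miR-411",
    "miR-451", "miR-485-5p", "miR-486", "miR-491", "miR-874", "miR-888",
)


@dataclasses.dataclass(frozen=True)
class Effect:
    """Additive Ct shift of one miRNA in one group (optionally one sex).

    A k-fold concentration increase maps to ``shift_ct = -log2(k)``.
    """

    mirna: str
    group: str
    shift_ct: float
    sex: str | None = None


@dataclasses.dataclass(frozen=True)
class CorrelationBlock:
    """A set of miRNAs sharing a within-block Spearman correlation target."""

    mirnas: tuple[str, ...]
    spearman: float = 0.85


def fold_to_ct(fold: float) -> float:
    """Ct shift equivalent to a fold-change in concentration (8x -> -3)."""
    if fold <= 0:
        raise ConfigurationError("fold change must be positive")
    return -float(np.log2(fold))


def _default_effects() -> tuple[Effect, ...]:
    # Study-flavoured ground truth: a few plasma-elevated (lower Ct)
    # miRNAs per disease, the 8-fold muscle miRNA in ALS, and one
    # female-restricted ALS effect to exercise the stratified analysis.
    return (
        Effect("miR-99b", "AD", -2.4),
        Effect("miR-9*", "AD", -2.0),
        Effect("miR-7", "AD", -1.6),
        Effect("miR-9*", "PD", -2.2),
        Effect("miR-99b", "PD", -1.8),
        Effect("miR-411", "PD", -1.6),
        Effect("miR-335", "FTD", -2.0),
        Effect("miR-99b", "FTD", -1.7),
        Effect("miR-491", "FTD", -1.4),
        Effect("miR-206", "ALS", fold_to_ct(8.0)),
        Effect("miR-338-3p", "ALS", -1.8),
        Effect("miR-99", "ALS", -1.5),
        Effect("miR-451", "ALS", -2.0, sex="F"),
    )


def _default_blocks(panel: Sequence[str]) -> tuple[CorrelationBlock, ...]:
    # Correlated background blocks at Spearman 0.85 among the brain-enriched
    # miRNAs that carry no disease effect (group shifts on one block member
    # would otherwise dilute the pooled-sample correlation below the 0.8
    # linkage threshold).  With the default panel this leaves 6 block
    # clusters + 10 effect-bearing singletons + 2 QC singletons = 18
    # clusters, i.e. 153 effective pairs -- the "about 160" regime of a
    # highly correlated panel.  The ubiquitous QC miRNAs stay uncorrelated.
    affected = {e.mirna for e in _default_effects()}
    background = [m for m in panel
                  if m not in ("miR-16", "miR-27a") and m not in affected]
    blocks = []
    pos = 0
    for size in [5, 4, 4, 4, 4, 4]:
        members = tuple(background[pos:pos + size])
        if len(members) >= 2:
            blocks.append(CorrelationBlock(members, 0.85))
        pos += size
    return tuple(blocks)


@dataclasses.dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic qRT-PCR case-control cohort."""

    mirnas: tuple[str, ...] = DEFAULT_PANEL
    group_sizes: dict = dataclasses.field(
        default_factory=lambda: {"control": 50, "AD": 50, "PD": 50,
                                 "FTD": 50, "ALS": 50})
    baseline_ct: dict | None = None  # per-miRNA mean Ct; None -> defaults
    between_sample_sd: float = 1.2  # Ct, biological + preparation spread
    replicate_sd: float = 0.25  # Ct, RT/PCR technical noise
    n_replicates: int = 3
    correlation_blocks: tuple[CorrelationBlock, ...] | None = None
    effects: tuple[Effect, ...] | None = None
    male_fraction: dict = dataclasses.field(
        default_factory=lambda: {"control": 24 / 50, "AD": 24 / 50,
                                 "PD": 35 / 50, "FTD": 28 / 50,
                                 "ALS": 36 / 50})
    age_mean: dict = dataclasses.field(
        default_factory=lambda: {"control": 64.1, "AD": 67.8, "PD": 66.8,
                                 "FTD": 63.1, "ALS": 59.6})
    age_sd: dict = dataclasses.field(
        default_factory=lambda: {"control": 9.8, "AD": 10.4, "PD": 7.7,
                                 "FTD": 6.9, "ALS": 10.8})
    age_range: tuple[float, float] = (25.0, 90.0)
    age_slopes: dict = dataclasses.field(default_factory=dict)  # mirna -> Ct/yr
    age_center: float = 65.0
    detection_limit: float = 37.0
    qc_outlier_rate: float = 0.02
    qc_outlier_shift: float = 4.0  # Ct added to every miRNA of an outlier prep
    seed: int = 0

    def __post_init__(self) -> None:
        self.mirnas = tuple(self.mirnas)
        if self.effects is None:
            self.effects = _default_effects()
        else:  # accept plain mappings (e.g. parsed YAML)
            self.effects = tuple(
                e if isinstance(e, Effect) else Effect(**e)
                for e in self.effects)
        if self.correlation_blocks is None:
            self.correlation_blocks = _default_blocks(self.mirnas)
        else:
            self.correlation_blocks = tuple(
                b if isinstance(b, CorrelationBlock)
                else CorrelationBlock(tuple(b["mirnas"]),
                                      b.get("spearman", 0.85))
                for b in self.correlation_blocks)
        if self.baseline_ct is None:
            base = {}
            others = [m for m in self.mirnas if m not in ("miR-16", "miR-27a")]
            levels = np.linspace(23.0, 33.5, len(others)) if others else []
            base.update({"miR-16": 21.5, "miR-27a": 22.3})
            base.update({m: round(float(v), 2) for m, v in zip(others, levels)})
            self.baseline_ct = {m: base[m] for m in self.mirnas if m in base}
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ConfigurationError("duplicate miRNA names in panel")
        if self.between_sample_sd <= 0 or self.replicate_sd < 0:
            raise ConfigurationError("noise SDs must be positive")
        if not 0 <= self.qc_outlier_rate <= 1:
            raise ConfigurationError("qc_outlier_rate must be in [0, 1]")
        seen: set[str] = set()
        for block in self.correlation_blocks:
            for m in block.mirnas:
                if m not in self.mirnas:
                    raise ConfigurationError(f"correlation block names unknown miRNA '{m}'")
                if m in seen:
                    raise ConfigurationError(f"miRNA '{m}' appears in two correlation blocks")
                seen.add(m)
            if not -1 < block.spearman < 1:
                raise ConfigurationError("block Spearman target must be in (-1, 1)")
        for eff in self.effects:
            if eff.mirna not in self.mirnas:
                raise ConfigurationError(f"effect names unknown miRNA '{eff.mirna}'")
            if eff.group not in self.group_sizes:
                raise ConfigurationError(f"effect names unknown group '{eff.group}'")
            if eff.sex not in (None, "M", "F"):
                raise ConfigurationError("effect sex must be None, 'M' or 'F'")
        # the correlation matrix must be positive definite
        np.linalg.cholesky(self.correlation_matrix())

    # -- derived structure -------------------------------------------------
    def correlation_matrix(self) -> np.ndarray:
        """Latent Pearson correlation implied by the Spearman block targets."""
        k = len(self.mirnas)
        idx = {m: i for i, m in enumerate(self.mirnas)}
        corr = np.eye(k)
        for block in self.correlation_blocks:
            # Gaussian copula: rho_pearson = 2 sin(pi * rho_spearman / 6)
            rho_p = 2.0 * np.sin(np.pi * block.spearman / 6.0)
            for a in block.mirnas:
                for b in block.mirnas:
                    if a != b:
                        corr[idx[a], idx[b]] = rho_p
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "correlation structure is not positive definite") from exc
        return corr

    def shift_matrix(self, group: str, sex: str | None = None) -> np.ndarray:
        """Total Ct shift per miRNA for one group (and optionally one sex)."""
        shift = np.zeros(len(self.mirnas))
        idx = {m: i for i, m in enumerate(self.mirnas)}
        for eff in self.effects:
            if eff.group != group:
                continue
            if eff.sex is not None and sex is not None and eff.sex != sex:
                continue
            if eff.sex is not None and sex is None:
                continue  # sex-restricted effects only count in their stratum
            shift[idx[eff.mirna]] += eff.shift_ct
        return shift


@dataclasses.dataclass
class GroundTruth:
    """Closed-form companion of a generated cohort."""

    config: SyntheticConfig
    effect_table: pd.DataFrame  # mirna, group, shift_ct, sex

    @property
    def sigma_mirna(self) -> float:
        """Effective per-miRNA SD of an aggregated (median-of-3) Ct value."""
        cfg = self.config
        rep_var = MEDIAN3_VAR * cfg.replicate_sd**2 if cfg.n_replicates == 3 \
            else cfg.replicate_sd**2 / cfg.n_replicates
        return float(np.sqrt(cfg.between_sample_sd**2 + rep_var))

    def pair_sigma_delta(self, pair: Pair) -> float:
        """Per-group SD of the pair's delta Ct (accounts for correlation)."""
        cfg = self.config
        idx = {m: i for i, m in enumerate(cfg.mirnas)}
        corr = cfg.correlation_matrix()
        rho = corr[idx[pair.numerator], idx[pair.denominator]]
        s2 = self.sigma_mirna**2
        return float(np.sqrt(max(2.0 * s2 * (1.0 - rho), 1e-12)))

    def pair_shift(self, group: str, pair: Pair, sex: str | None = None) -> float:
        """Case-minus-control mean delta Ct of a pair for one group."""
        shift = self.config.shift_matrix(group, sex)
        idx = {m: i for i, m in enumerate(self.config.mirnas)}
        return float(shift[idx[pair.numerator]] - shift[idx[pair.denominator]])

    def pair_auc(self, group: str, pair: Pair, sex: str | None = None) -> float:
        """Theoretical oriented AUC of a pair for group vs control."""
        d = abs(self.pair_shift(group, pair, sex))
        return theoretical_pair_auc(d, self.pair_sigma_delta(pair))

    def affected_pairs(self, group: str) -> list[Pair]:
        """Pairs with a non-zero (sex-unrestricted) mean shift in ``group``."""
        names = sorted(self.config.mirnas)
        out = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if abs(self.pair_shift(group, Pair(a, b))) > 1e-12:
                    out.append(Pair(a, b))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sigma_mirna": self.sigma_mirna,
            "effects": self.effect_table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def theoretical_pair_auc(d: float, sigma: float) -> float:
    """AUC of a binormal equal-variance delta-Ct model: Phi(d / (sigma*sqrt(2))).

    ``d`` is the case-minus-control mean difference and ``sigma`` the
    common per-group SD of the delta Ct.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    return float(sps.norm.cdf(d / (sigma * np.sqrt(2.0))))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SyntheticConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one cohort: replicate-level Ct table, metadata and ground truth.

    Deterministic given ``cfg.seed``.  Replicate Ct values above the
    detection limit are masked (reported as missing), mirroring the
    exclusion rule applied during analysis.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.mirnas)
    k = len(names)
    baseline = np.array([cfg.baseline_ct[m] for m in names])
    chol = np.linalg.cholesky(cfg.correlation_matrix())
    slopes = np.array([cfg.age_slopes.get(m, 0.0) for m in names])

    rep_rows = []
    meta_rows = []
    for group, n in cfg.group_sizes.items():
        n_male = int(round(n * cfg.male_fraction.get(group, 0.5)))
        sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sexes)
        ages = np.clip(
            rng.normal(cfg.age_mean.get(group, 65.0),
                       cfg.age_sd.get(group, 10.0), n),
            *cfg.age_range,
        ).round(1)

        z = rng.standard_normal((n, k)) @ chol.T
        latent = baseline + cfg.between_sample_sd * z
        latent += np.outer(ages - cfg.age_center, slopes)
        for sex in ("M", "F"):
            rows = sexes == sex
            latent[rows] += cfg.shift_matrix(group, sex)
        outlier = rng.random(n) < cfg.qc_outlier_rate
        latent[outlier] += cfg.qc_outlier_shift

        reps = latent[None, :, :] + rng.normal(
            0.0, cfg.replicate_sd, (cfg.n_replicates, n, k))
        reps = np.where(reps > cfg.detection_limit, np.nan, reps)

        ids = [f"{group}-{i + 1:03d}" for i in range(n)]
        for r in range(cfg.n_replicates):
            rep_rows.append(pd.DataFrame({
                "sample_id": np.repeat(ids, k),
                "mirna": np.tile(names, n),
                "replicate_index": r + 1,
                "ct": reps[r].ravel().round(4),
            }))
        meta_rows.append(pd.DataFrame({
            "sample_id": ids,
            "group": group,
            "subgroup": "",
            "sex": sexes,
            "age": ages,
            "split": "unassigned",
        }))

    replicates = (
        pd.concat(rep_rows, ignore_index=True)
        .sort_values(["sample_id", "mirna", "replicate_index"],
                     kind="stable")
        .reset_index(drop=True)
    )
    meta = pd.concat(meta_rows, ignore_index=True)
    effect_table = pd.DataFrame(
        [dataclasses.asdict(e) for e in cfg.effects],
        columns=["mirna", "group", "shift_ct", "sex"],
    )
    return replicates, meta, GroundTruth(cfg, effect_table)


def write_cohort(outdir: str | Path, replicates: pd.DataFrame,
                 meta: pd.DataFrame, truth: GroundTruth) -> dict[str, Path]:
    """Write the generated cohort in the CSV dialects the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct_table": outdir / "ct_replicates.csv",
        "metadata": outdir / "metadata.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    out = replicates.copy()
    out["ct"] = out["ct"].map(
        lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(paths["ct_table"], index=False)
    meta.to_csv(paths["metadata"], index=False)
    truth.to_json(paths["ground_truth"])
    return paths


# ---------------------------------------------------------------------------
# convenience configurations
# ---------------------------------------------------------------------------

def two_group_config(
    n_per_group: int = 50,
    mirnas: Sequence[str] | None = None,
    effects: Sequence[Effect] = (),
    correlation_blocks: Sequence[CorrelationBlock] = (),
    between_sample_sd: float = 1.2,
    replicate_sd: float = 0.25,
    baseline_ct: dict | None = None,
    male_fraction: float = 0.5,
    qc_outlier_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticConfig:
    """A compact case/control configuration for simulation studies."""
    panel = tuple(mirnas) if mirnas is not None else DEFAULT_PANEL
    return SyntheticConfig(
        mirnas=panel,
        group_sizes={"control": n_per_group, "case": n_per_group},
        baseline_ct=baseline_ct,
        between_sample_sd=between_sample_sd,
        replicate_sd=replicate_sd,
        correlation_blocks=tuple(correlation_blocks),
        effects=tuple(effects),
        male_fraction={"control": male_fraction, "case": male_fraction},
        age_mean={"control": 64.0, "case": 64.0},
        age_sd={"control": 9.0, "case": 9.0},
        qc_outlier_rate=qc_outlier_rate,
        seed=seed,
    )


def null_two_group_config(n_per_group: int = 50, seed: int = 0,
                          with_correlation: bool = True) -> SyntheticConfig:
    """Zero-effect two-group cohort under the default study conditions."""
    return two_group_config(
        n_per_group=n_per_group,
        effects=(),
        correlation_blocks=(_default_blocks(DEFAULT_PANEL)
                            if with_correlation else ()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CalibrationReport:
    """Operating characteristics of the multiplicity machinery under the null."""

    n_reps: int
    n_pairs: int
    alpha: float
    bonferroni_threshold: float
    per_pair_rejection_rate: float
    family_wise_error_rate: float
    frac_rejected_per_rep: np.ndarray
    min_p_per_rep: np.ndarray


def null_calibration_experiment(cfg: SyntheticConfig, n_reps: int,
                                alpha: float = 0.05) -> CalibrationReport:
    """Repeatedly run the pair pipeline on zero-effect cohorts.

    Each replicate simulates a fresh cohort from ``cfg`` (reseeded from
    ``cfg.seed``), aggregates replicates, applies the detection limit and
    QC filter, computes the Mann-Whitney p for every pair, and records the
    fraction of pairs rejected at raw ``alpha`` and whether any pair falls
    under the Bonferroni threshold ``alpha / n_pairs``.
    """
    if any(abs(e.shift_ct) > 0 for e in cfg.effects):
        raise ConfigurationError("null calibration requires a zero-effect config")
    groups = list(cfg.group_sizes)
    if len(groups) != 2:
        raise ConfigurationError("null calibration expects exactly two groups")
    n_mirnas = len(cfg.mirnas)
    n_pairs = n_mirnas * (n_mirnas - 1) // 2
    threshold = alpha / n_pairs

    children = np.random.SeedSequence(cfg.seed).spawn(n_reps)
    fracs = np.empty(n_reps)
    min_ps = np.empty(n_reps)
    for i, child in enumerate(children):
        rep_cfg = dataclasses.replace(
            cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        replicates, meta, _ = simulate_cohort(rep_cfg)
        matrix = apply_detection_limit(
            aggregate_replicates(replicates, rep_cfg.detection_limit))
        if all(q in matrix.ct.columns for q in ("miR-16", "miR-27a")):
            matrix, _ = qc_filter_samples(matrix)
        grp = meta.set_index("sample_id")["group"].loc[matrix.sample_ids]
        labels = (grp == groups[1]).to_numpy()
        pvals = pairwise_mw_pvalues(matrix, labels).to_numpy()
        fracs[i] = float(np.mean(pvals < alpha))
        min_ps[i] = float(np.min(pvals))

    return CalibrationReport(
        n_reps=n_reps,
        n_pairs=n_pairs,
        alpha=alpha,
        bonferroni_threshold=threshold,
        per_pair_rejection_rate=float(fracs.mean()) if n_reps else float("nan"),
        family_wise_error_rate=(float(np.mean(min_ps < threshold))
                                if n_reps else float("nan")),
        frac_rejected_per_rep=fracs,
        min_p_per_rep=min_ps,
    )
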