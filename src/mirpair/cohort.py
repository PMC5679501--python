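"""Reading, aggregation, QC filtering and splitting of qRT-PCR cohort data.

The raw unit of measurement is a single reverse-transcription replicate:
one Ct value per (sample, miRNA, replicate) triple.  Replicates are
aggregated to a per-sample Ct matrix, values beyond the instrument
detection limit are masked, samples whose ubiquitous QC miRNAs deviate
from the batch average are removed, and each diagnosis group is split
into training and confirmation halves balanced by sex and age.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FormatError,
    InsufficientDataError,
    IntegrityError,
)

REPLICATE_COLUMNS = ("sample_id", "mirna", "replicate_index", "ct")
METADATA_COLUMNS = ("sample_id", "group", "subgroup", "sex", "age", "split")
DEFAULT_QC_MIRNAS = ("miR-16", "miR-27a")
DEFAULT_DETECTION_LIMIT = 37.0

#: sentinel strings that qPCR exports use for a failed amplification
_MISSING_TOKENS = {"", "na", "nan", "n/a", "undetermined", "undet", "none"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CtMatrix:
    """Samples x miRNAs matrix of aggregated Ct values.

    Missing measurements (failed or censored amplifications) are NaN.
    ``batches`` optionally maps each sample to the batch (input file or
    explicit batch column) it was measured in; QC statistics are computed
    per batch.
    """

    ct: pd.DataFrame
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    batches: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.ct.index.has_duplicates:
            raise IntegrityError("duplicate sample ids in Ct matrix")
        if self.ct.columns.has_duplicates:
            raise IntegrityError("duplicate miRNA names in Ct matrix")
        if self.batches is not None:
            self.batches = self.batches.reindex(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.ct.columns)

    def subset(self, samples: Sequence[str]) -> "CtMatrix":
        """Restrict to the given samples, preserving matrix order."""
        keep = [s for s in self.ct.index if s in set(samples)]
        batches = self.batches.loc[keep] if self.batches is not None else None
        return CtMatrix(self.ct.loc[keep], self.detection_limit, batches)

    def to_csv(self, path: str | Path) -> None:
        self.ct.to_csv(path, index_label="sample_id")


@dataclasses.dataclass
class QCReport:
    """Outcome of the ubiquitous-miRNA quality-control filter."""

    qc_mirnas: tuple[str, ...]
    k_sd: float
    batch_stats: pd.DataFrame  # columns: batch, mirna, mean, sd, n
    sample_flags: pd.Series  # bool per sample, True = passed
    failed_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "qc_mirnas": list(self.qc_mirnas),
            "k_sd": self.k_sd,
            "batch_stats": self.batch_stats.to_dict(orient="records"),
            "n_pass": int(self.sample_flags.sum()),
            "n_fail": len(self.failed_samples),
            "failed_samples": list(self.failed_samples),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _coerce_ct(raw: pd.Series) -> pd.Series:
    """Map qPCR export cells to float Ct; sentinel/non-numeric cells -> NaN."""
    cleaned = raw.astype(str).str.strip()
    cleaned = cleaned.mask(cleaned.str.lower().isin(_MISSING_TOKENS))
    return pd.to_numeric(cleaned, errors="coerce")


def validate_replicate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check replicate-level invariants; returns the table unchanged."""
    for col in REPLICATE_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"replicate table is missing column '{col}'")
    dup = table.duplicated(subset=["sample_id", "mirna", "replicate_index"])
    if dup.any():
        first = table.loc[dup.idxmax(), ["sample_id", "mirna", "replicate_index"]]
        raise IntegrityError(
            "duplicate replicate record for "
            f"({first['sample_id']}, {first['mirna']}, {first['replicate_index']})"
        )
    bad = table["ct"].notna() & (table["ct"] <= 0)
    if bad.any():
        raise IntegrityError("Ct values must be positive or missing")
    return table


def load_ct_table(path: str | Path, layout: str = "long") -> pd.DataFrame:
    """Load a Ct table in ``long`` or ``wide`` layout into replicate records.

    Long layout needs columns ``sample_id``, ``mirna``, ``ct`` and
    optionally ``replicate_index`` (default 1) and ``batch``.  Wide layout
    needs a ``sample_id`` column and one column per miRNA (single
    measurement, replicate_index 1).  Non-numeric cells such as
    "Undetermined" become missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_table(path)

    if layout == "long":
        for col in ("sample_id", "mirna", "ct"):
            if col not in raw.columns:
                raise FormatError(f"long Ct table is missing column '{col}'")
        table = pd.DataFrame(
            {
                "sample_id": raw["sample_id"].astype(str).str.strip(),
                "mirna": raw["mirna"].astype(str).str.strip(),
                "replicate_index": (
                    pd.to_numeric(raw["replicate_index"], errors="raise").astype(int)
                    if "replicate_index" in raw.columns
                    else 1
                ),
                "ct": _coerce_ct(raw["ct"]),
            }
        )
        if "batch" in raw.columns:
            table["batch"] = raw["batch"].astype(str).str.strip()
    elif layout == "wide":
        if "sample_id" not in raw.columns:
            raise FormatError("wide Ct table is missing column 'sample_id'")
        mirna_cols = [c for c in raw.columns if c not in ("sample_id", "batch")]
        if not mirna_cols:
            raise FormatError("wide Ct table has no miRNA columns")
        table = raw.melt(
            id_vars=[c for c in ("sample_id", "batch") if c in raw.columns],
            value_vars=mirna_cols,
            var_name="mirna",
            value_name="ct",
        )
        table["sample_id"] = table["sample_id"].astype(str).str.strip()
        table["ct"] = _coerce_ct(table["ct"])
        table["replicate_index"] = 1
        order = ["sample_id", "mirna", "replicate_index", "ct"]
        if "batch" in table.columns:
            order.append("batch")
        table = table[order]
    else:
        raise ConfigurationError(f"unknown layout '{layout}' (expected long or wide)")

    return validate_replicate_table(table.reset_index(drop=True))


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Load a sample metadata CSV; missing optional columns get defaults."""
    raw = _read_table(path)
    for col in ("sample_id", "group", "sex", "age"):
        if col not in raw.columns:
            raise FormatError(f"metadata table is missing column '{col}'")
    meta = pd.DataFrame(
        {
            "sample_id": raw["sample_id"].astype(str).str.strip(),
            "group": raw["group"].astype(str).str.strip(),
            "subgroup": raw.get("subgroup", pd.Series("", index=raw.index)).astype(str),
            "sex": raw["sex"].astype(str).str.strip().str.upper(),
            "age": pd.to_numeric(raw["age"], errors="coerce"),
            "split": raw.get("split", pd.Series("unassigned", index=raw.index)).astype(str),
        }
    )
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if meta["sample_id"].duplicated().any():
        raise IntegrityError("duplicate sample_id in metadata")
    if not meta["sex"].isin(["M", "F"]).all():
        raise IntegrityError("sex must be 'M' or 'F'")
    if (meta["age"].dropna() <= 0).any():
        raise IntegrityError("age must be positive")
    meta = meta.copy()
    meta.loc[~meta["split"].isin(["training", "confirmation"]), "split"] = "unassigned"
    return meta.reset_index(drop=True)


# ---------------------------------------------------------------------------
# aggregation and masking
# ---------------------------------------------------------------------------

def aggregate_replicates(table: pd.DataFrame,
                         detection_limit: float = DEFAULT_DETECTION_LIMIT) -> CtMatrix:
    """Collapse RT replicates to one Ct per (sample, miRNA) by the median.

    The median of the non-missing replicates is used; the entry is missing
    only if every replicate is missing.  Sample and miRNA order follow
    first appearance in the table.
    """
    validate_replicate_table(table)
    sample_order = table["sample_id"].drop_duplicates().tolist()
    mirna_order = table["mirna"].drop_duplicates().tolist()
    ct = (
        table.pivot_table(index="sample_id", columns="mirna", values="ct",
                          aggfunc="median")
        .reindex(index=sample_order, columns=mirna_order)
    )
    ct.index.name = "sample_id"
    ct.columns.name = None

    batches = None
    if "batch" in table.columns:
        per_sample = table.groupby("sample_id")["batch"].unique()
        if per_sample.map(len).max() > 1:
            raise IntegrityError("a sample maps to more than one batch")
        batches = per_sample.map(lambda v: v[0]).reindex(sample_order)
    return CtMatrix(ct, detection_limit=detection_limit, batches=batches)


def apply_detection_limit(m: CtMatrix, limit: float | None = None) -> CtMatrix:
    """Mask Ct values beyond the detection limit (strictly greater than).

    A Ct exactly at the limit is retained.  Idempotent.
    """
    limit = m.detection_limit if limit is None else float(limit)
    if limit <= 0:
        raise ConfigurationError("detection limit must be positive")
    ct = m.ct.where(~(m.ct > limit))
    return CtMatrix(ct, detection_limit=limit, batches=m.batches)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter_samples(
    m: CtMatrix,
    qc_mirnas: Iterable[str] = DEFAULT_QC_MIRNAS,
    k_sd: float = 2.0,
) -> tuple[CtMatrix, QCReport]:
    """Drop samples whose ubiquitous QC miRNAs deviate from the batch mean.

    A sample passes iff, for every QC miRNA, its Ct is present and lies
    within ``mean +/- k_sd * SD`` (inclusive) of that QC miRNA in the
    sample's batch.  Batch statistics are computed over all loaded samples
    of the batch before any exclusion, non-iteratively.
    """
    qc_mirnas = tuple(qc_mirnas)
    for name in qc_mirnas:
        if name not in m.ct.columns:
            raise ConfigurationError(f"QC miRNA '{name}' not in panel")
    if k_sd < 0:
        raise ConfigurationError("k_sd must be non-negative")

    batches = (
        m.batches.fillna("batch-1")
        if m.batches is not None
        else pd.Series("batch-1", index=m.ct.index)
    )

    stats_rows = []
    flags = pd.Series(True, index=m.ct.index)
    for batch in batches.drop_duplicates():
        idx = batches.index[batches == batch]
        for name in qc_mirnas:
            vals = m.ct.loc[idx, name]
            finite = vals.dropna()
            if len(finite) < 3:
                raise InsufficientDataError(
                    f"batch '{batch}' has fewer than 3 finite values for {name}"
                )
            mean, sd = float(finite.mean()), float(finite.std(ddof=1))
            stats_rows.append(
                {"batch": batch, "mirna": name, "mean": mean, "sd": sd,
                 "n": int(len(finite))}
            )
            ok = vals.notna() & ((vals - mean).abs() <= k_sd * sd)
            flags.loc[idx] &= ok

    failed = list(flags.index[~flags])
    filtered = CtMatrix(
        m.ct.loc[flags],
        detection_limit=m.detection_limit,
        batches=m.batches.loc[flags] if m.batches is not None else None,
    )
    report = QCReport(
        qc_mirnas=qc_mirnas,
        k_sd=float(k_sd),
        batch_stats=pd.DataFrame(stats_rows),
        sample_flags=flags,
        failed_samples=failed,
    )
    return filtered, report


# ---------------------------------------------------------------------------
# training / confirmation split
# ---------------------------------------------------------------------------

def split_train_confirm(meta: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign each sample to the training or confirmation half of its group.

    Within every (group, sex) cell samples are sorted by age, consecutive
    age-adjacent pairs are split one-to-each-side at random, and leftover
    singletons alternate starting with training, so each half matches the
    other in sex composition and age profile and the group sizes differ by
    at most one (training gets the extra).
    """
    meta = validate_metadata(meta)
    rng = np.random.default_rng(seed)
    split = pd.Series("unassigned", index=meta.index)

    for group in sorted(meta["group"].unique()):
        g_rows = meta.index[meta["group"] == group]
        if len(g_rows) < 2:
            raise InsufficientDataError(f"group '{group}' has fewer than 2 samples")
        leftovers: list[int] = []
        for sex in sorted(meta.loc[g_rows, "sex"].unique()):
            rows = meta.loc[g_rows].loc[meta.loc[g_rows, "sex"] == sex]
            order = rows.sort_values(["age", "sample_id"]).index.to_list()
            for i in range(0, len(order) - 1, 2):
                first_to_training = bool(rng.random() < 0.5)
                split.loc[order[i]] = "training" if first_to_training else "confirmation"
                split.loc[order[i + 1]] = "confirmation" if first_to_training else "training"
            if len(order) % 2:
                leftovers.append(order[-1])
        # alternate leftover singletons, training first, to keep group halves
        # within one sample of each other
        for j, row in enumerate(leftovers):
            split.loc[row] = "training" if j % 2 == 0 else "confirmation"

    out = meta.copy()
    out["split"] = split
    return out
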