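"""Exhaustive miRNA-pair (delta-Ct ratio) statistics and candidate selection.

A biomarker here is the concentration ratio of two miRNAs, measured as
``delta Ct = Ct_numerator - Ct_denominator`` and displayed as
``2**(-delta Ct) * 100``.  Every unordered pair of panel miRNAs is scored
by rank AUC and a two-sided Mann-Whitney U test, oriented so the ratio is
larger in the case group, and gated by an AUC threshold together with a
Bonferroni p threshold whose test count is reduced for correlated miRNAs
(single-linkage clusters at Spearman rho >= 0.8).
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cohort import CtMatrix
from .exceptions import InsufficientDataError, IntegrityError


class Pair(NamedTuple):
    """An oriented miRNA pair; the ratio is numerator over denominator."""

    numerator: str
    denominator: str

    def flipped(self) -> "Pair":
        return Pair(self.denominator, self.numerator)

    @property
    def label(self) -> str:
        return f"{self.numerator}/{self.denominator}"


@dataclasses.dataclass
class PairValues:
    """Per-sample delta-Ct values of one pair (NaN where either Ct is missing)."""

    pair: Pair
    delta_ct: pd.Series

    @property
    def ratio(self) -> pd.Series:
        """Display-scale ratio 2**(-delta Ct) * 100."""
        return 2.0 ** (-self.delta_ct) * 100.0

    @property
    def complete(self) -> pd.Series:
        return self.delta_ct.notna()

    def flipped(self) -> "PairValues":
        return PairValues(self.pair.flipped(), -self.delta_ct)


@dataclasses.dataclass
class CutoffMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclasses.dataclass
class PairStat:
    """Discrimination statistics of one oriented pair on one dataset.

    ``cutoff`` is on the delta-Ct scale with the convention that a sample
    is called a case when its delta Ct is <= cutoff (equivalently its
    display ratio is >= the corresponding ratio cutoff).
    """

    pair: Pair
    auc: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_case: int
    n_control: int
    dataset_tag: str = "training"
    selected: bool = False

    def as_record(self) -> dict:
        rec = dataclasses.asdict(self)
        rec["pair"] = self.pair.label
        return rec


@dataclasses.dataclass
class MultiplicityPolicy:
    """Bonferroni policy with a correlation-reduced effective test count."""

    alpha: float
    n_pairs_nominal: int
    rho_threshold: float
    n_pairs_effective: int
    p_threshold: float

    @classmethod
    def nominal(cls, n_mirnas: int, alpha: float = 0.05,
                rho_threshold: float = 0.8) -> "MultiplicityPolicy":
        """Policy ignoring inter-miRNA correlation (all pairs counted)."""
        n_pairs = n_mirnas * (n_mirnas - 1) // 2
        return cls(alpha, n_pairs, rho_threshold, n_pairs, alpha / n_pairs)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

def enumerate_pairs(panel: Iterable[str]) -> list[Pair]:
    """All n(n-1)/2 unordered pairs of panel miRNAs, lexicographically."""
    names = list(panel)
    if len(set(names)) != len(names):
        raise IntegrityError("panel contains duplicate miRNA names")
    if len(names) < 2:
        raise InsufficientDataError("need at least 2 miRNAs to form pairs")
    return [Pair(a, b) for a, b in itertools.combinations(sorted(names), 2)]


def pair_delta_ct(m: CtMatrix, pair: Pair) -> PairValues:
    """Per-sample delta Ct for a pair; missing where either miRNA is missing."""
    for name in pair:
        if name not in m.ct.columns:
            raise KeyError(f"miRNA '{name}' not in Ct matrix")
    delta = m.ct[pair.numerator] - m.ct[pair.denominator]
    return PairValues(pair, delta)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _split_classes(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must have the same length")
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    case, ctrl = v[y], v[~y]
    if len(case) == 0 or len(ctrl) == 0:
        raise InsufficientDataError("both classes need at least one finite value")
    return case, ctrl


def rank_auc(values, labels) -> float:
    """Rank AUC: probability a random case exceeds a random control, ties 1/2.

    Equals U / (n_case * n_control) for the Mann-Whitney U statistic and
    the trapezoidal area under the empirical ROC curve.
    """
    case, ctrl = _split_classes(values, labels)
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    n1 = len(case)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * len(ctrl)))


def mann_whitney_p(values, labels) -> float:
    """Two-sided Mann-Whitney U p value.

    Exact by enumeration for small tie-free problems (n1*n2 <= 400); the
    normal approximation with tie and continuity correction otherwise.
    """
    case, ctrl = _split_classes(values, labels)
    pooled = np.concatenate([case, ctrl])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if tie_free and len(case) * len(ctrl) <= 400 else "asymptotic"
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    return float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))


def orient_pair(values: PairValues, labels) -> PairValues:
    """Flip the pair so its display ratio is larger in the case group.

    Orientation is chosen so the rank AUC of the oriented ratio is >= 0.5;
    an exact AUC tie is broken by comparing class medians, and if those tie
    too the input orientation is kept.
    """
    score = -values.delta_ct  # monotone in the display ratio
    auc = rank_auc(score, labels)
    if auc > 0.5:
        return values
    if auc < 0.5:
        return values.flipped()
    case, ctrl = _split_classes(score, labels)
    if np.median(case) < np.median(ctrl):
        return values.flipped()
    return values


def best_accuracy_cutoff(values, labels) -> CutoffMetrics:
    """Scan all ROC cutoffs and return the one with the best overall accuracy.

    A sample is called a case when its value is >= the cutoff (inclusive).
    Candidate cutoffs are midpoints between adjacent sorted unique values
    plus -inf/+inf.  Accuracy ties are broken by the larger Youden J, then
    by the lowest cutoff.
    """
    case, ctrl = _split_classes(values, labels)
    n1, n0 = len(case), len(ctrl)
    uniq = np.unique(np.concatenate([case, ctrl]))
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    cands = np.concatenate([[-np.inf], mids, [np.inf]])

    case_sorted, ctrl_sorted = np.sort(case), np.sort(ctrl)
    tp = n1 - np.searchsorted(case_sorted, cands, side="left")
    fp = n0 - np.searchsorted(ctrl_sorted, cands, side="left")
    sens = tp / n1
    spec = (n0 - fp) / n0
    acc = (tp + (n0 - fp)) / (n1 + n0)
    youden = sens + spec - 1.0

    # lexicographic argmax: accuracy, then Youden J, then lowest cutoff
    best = max(range(len(cands)), key=lambda i: (acc[i], youden[i], -cands[i]))
    return CutoffMetrics(float(cands[best]), float(sens[best]),
                         float(spec[best]), float(acc[best]))


# ---------------------------------------------------------------------------
# per-pair statistics
# ---------------------------------------------------------------------------

def pair_statistics(values: PairValues, labels, dataset_tag: str = "training",
                    orient: bool = True) -> PairStat:
    """AUC, Mann-Whitney p and best-accuracy cutoff metrics for one pair.

    With ``orient=True`` the pair is first oriented on these data; with
    ``orient=False`` a previously fixed orientation is evaluated as-is
    (used for confirmation/combined evaluation of training selections).
    """
    labels = np.asarray(labels, dtype=bool)
    if orient:
        values = orient_pair(values, labels)
    score = -values.delta_ct
    auc = rank_auc(score, labels)
    p = mann_whitney_p(score, labels)
    cm = best_accuracy_cutoff(score, labels)
    keep = np.isfinite(np.asarray(score, dtype=float))
    return PairStat(
        pair=values.pair,
        auc=auc,
        p_value=p,
        cutoff=-cm.cutoff,  # back to the delta-Ct scale (case: delta <= cutoff)
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        n_case=int(labels[keep].sum()),
        n_control=int((~labels[keep]).sum()),
        dataset_tag=dataset_tag,
    )


def screen_pairs(m: CtMatrix, labels, dataset_tag: str = "training",
                 min_complete_frac: float = 0.7) -> list[PairStat]:
    """Oriented statistics for every analyzable panel pair.

    A pair is analyzable when at least ``min_complete_frac`` of each class
    has complete (both-miRNA) values; others are skipped.
    """
    labels = np.asarray(labels, dtype=bool)
    out = []
    for pair in enumerate_pairs(m.ct.columns):
        values = pair_delta_ct(m, pair)
        comp = values.complete.to_numpy()
        n_case, n_ctrl = labels.sum(), (~labels).sum()
        if n_case == 0 or n_ctrl == 0:
            raise InsufficientDataError("both classes must be present")
        if (comp[labels].sum() < min_complete_frac * n_case
                or comp[~labels].sum() < min_complete_frac * n_ctrl):
            continue
        if comp[labels].sum() == 0 or comp[~labels].sum() == 0:
            continue
        out.append(pair_statistics(values, labels, dataset_tag))
    return out


def evaluate_pairs(m: CtMatrix, pairs: Sequence[Pair], labels,
                   dataset_tag: str) -> list[PairStat]:
    """Evaluate already-oriented pairs on another dataset without reorienting."""
    return [
        pair_statistics(pair_delta_ct(m, p), labels, dataset_tag, orient=False)
        for p in pairs
    ]


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def effective_test_count(m: CtMatrix, rho_threshold: float = 0.8,
                         alpha: float = 0.05) -> MultiplicityPolicy:
    """Correlation-reduced Bonferroni policy for the pair family.

    miRNA Ct profiles are clustered by single linkage at Spearman
    rho >= ``rho_threshold`` (pairwise-complete observations); with c
    clusters the effective number of tests is c(c-1)/2.  Constant profiles
    are excluded with a warning; a degenerate reduction to fewer than two
    clusters falls back to the nominal count.
    """
    if m.ct.shape[0] < 3:
        raise InsufficientDataError("need at least 3 samples for correlations")
    n = m.ct.shape[1]
    n_nominal = n * (n - 1) // 2

    usable = [c for c in m.ct.columns if m.ct[c].dropna().nunique() > 1]
    dropped = [c for c in m.ct.columns if c not in usable]
    if dropped:
        warnings.warn(
            f"excluding constant miRNA profiles from clustering: {dropped}",
            stacklevel=2,
        )

    rho = m.ct[usable].corr(method="spearman", min_periods=3)
    adj = (rho.to_numpy() >= rho_threshold)
    np.fill_diagonal(adj, True)
    n_clusters, _ = connected_components(csr_matrix(adj), directed=False)

    n_eff = n_clusters * (n_clusters - 1) // 2
    if n_eff < 1:
        warnings.warn(
            "correlation clustering collapsed the panel to a single cluster; "
            "falling back to the nominal pair count",
            stacklevel=2,
        )
        n_eff = n_nominal
    return MultiplicityPolicy(
        alpha=alpha,
        n_pairs_nominal=n_nominal,
        rho_threshold=rho_threshold,
        n_pairs_effective=n_eff,
        p_threshold=alpha / n_eff,
    )


def select_pairs(stats_list: Sequence[PairStat], auc_threshold: float,
                 policy: MultiplicityPolicy,
                 use_p_gate: bool = True) -> list[PairStat]:
    """Candidate pairs passing the AUC gate (>=) and the Bonferroni p gate (<).

    Returned sorted by descending AUC (pair label breaks ties); each
    returned stat is a copy flagged ``selected=True``.
    """
    chosen = [
        s for s in stats_list
        if s.auc >= auc_threshold
        and (not use_p_gate or s.p_value < policy.p_threshold)
    ]
    chosen.sort(key=lambda s: (-s.auc, s.pair.label))
    return [dataclasses.replace(s, selected=True) for s in chosen]


def stats_to_frame(stats_list: Sequence[PairStat], **extra) -> pd.DataFrame:
    """Tabulate PairStat records; ``extra`` adds constant annotation columns."""
    records = [s.as_record() for s in stats_list]
    frame = pd.DataFrame(records)
    for key, val in extra.items():
        frame[key] = val
    return frame


# ---------------------------------------------------------------------------
# vectorized screening (used by large simulation studies)
# ---------------------------------------------------------------------------

def all_pair_deltas(m: CtMatrix) -> tuple[np.ndarray, list[Pair]]:
    """Delta-Ct matrix (samples x pairs) for every panel pair.

    Column order matches :func:`enumerate_pairs` on the panel.
    """
    names = sorted(m.ct.columns)
    ct = m.ct[names].to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(names), k=1)
    deltas = ct[:, iu] - ct[:, ju]
    pairs = [Pair(names[i], names[j]) for i, j in zip(iu, ju)]
    return deltas, pairs


def pairwise_mw_pvalues(m: CtMatrix, labels) -> pd.Series:
    """Two-sided asymptotic Mann-Whitney p for every pair, vectorized.

    Matches :func:`mann_whitney_p` in its large-sample regime (tie and
    continuity corrected normal approximation); intended for simulation
    studies that score many cohorts.
    """
    labels = np.asarray(labels, dtype=bool)
    deltas, pairs = all_pair_deltas(m)
    case, ctrl = deltas[labels], deltas[~labels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(case, ctrl, axis=0, alternative="two-sided",
                                 method="asymptotic", nan_policy="omit")
    p = np.clip(np.asarray(res.pvalue, dtype=float), np.finfo(float).tiny, 1.0)
    return pd.Series(p, index=[pr.label for pr in pairs])
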