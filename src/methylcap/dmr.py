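"""Feature-level differential methylation.

For each genomic feature (CpG island, shore, promoter, ...) the RPM of every
bin overlapping the feature is summed per sample; groups are compared per
feature with a two-sided Wilcoxon rank-sum test and q-values come from
Benjamini–Hochberg step-up applied across all features of the feature set.
A feature is called a DMR when q <= the FDR cutoff (default 0.05).

The rank-sum test uses midranks for ties, exact p-values by full enumeration
of group assignments when the combined sample size is at most 12, and the
normal approximation with tie correction and 0.5 continuity correction
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import special, stats

from .alignment_io import BinCountVector
from .genome_index import GenomeIndex

__all__ = [
    "FeatureSet",
    "read_feature_bed",
    "feature_rpm_sum",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "call_dmrs",
]

EXACT_MAX_N = 12


@dataclass
class FeatureSet:
    """Named set of 0-based half-open genomic intervals with unique ids."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end, feature_id

    def __post_init__(self) -> None:
        iv = self.intervals
        if (iv["end"] <= iv["start"]).any():
            raise ValueError("feature intervals must satisfy end > start")
        if iv["feature_id"].duplicated().any():
            raise ValueError("feature ids must be unique")


def read_feature_bed(path: str, name: str | None = None) -> FeatureSet:
    """Load a BED4 feature file (chrom, start, end, feature_id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "feature_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "feature_id": str},
    )
    return FeatureSet(name=name or path, intervals=df)


def feature_rpm_sum(
    sample_bins: BinCountVector, features: FeatureSet, index: GenomeIndex
) -> pd.Series:
    """Sum RPM over every bin overlapping each feature by >= 1 bp.

    A bin straddling two features contributes fully to both.  Returns a
    Series indexed by feature_id in the feature file's order.
    """
    if sample_bins.rpm is None:
        raise ValueError("sample bins must be RPM-normalized")
    offsets = index.bin_offsets
    bs = index.bin_size
    out = np.empty(len(features.intervals), dtype=float)
    rpm = sample_bins.rpm
    for i, row in enumerate(features.intervals.itertuples(index=False)):
        if row.chrom not in offsets:
            raise ValueError(f"feature contig not in genome index: {row.chrom}")
        off = offsets[row.chrom]
        nb = index.n_bins(row.chrom)
        b0 = row.start // bs
        b1 = min((row.end - 1) // bs, nb - 1)
        out[i] = rpm[off + b0 : off + b1 + 1].sum()
    return pd.Series(out, index=features.intervals["feature_id"].to_numpy())


def _rank_sum_exact_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided permutation p over all C(n, n_a) group-A assignments."""
    n = ranks.size
    mean = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mean)
    hits = 0
    for idx in combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        if abs(w - mean) >= dev - 1e-9:
            hits += 1
    return hits / comb(n, n_a)


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the midrank sum of ``group_a``.  Exact
    enumeration is used for combined n <= 12; larger samples use the normal
    approximation with tie correction and continuity correction.  Identical
    values across both groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    w = float(ranks[:n_a].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    if n <= EXACT_MAX_N:
        return w, float(_rank_sum_exact_p(ranks, n_a, w))
    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    diff = w - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * special.ndtr(-abs(z))))
    return w, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_dmrs(
    sample_feature_sums: pd.DataFrame,
    groups: dict[str, str],
    features: FeatureSet,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Test every feature for a group difference in summed RPM.

    ``sample_feature_sums`` is features x samples (rows indexed by
    feature_id, columns by sample_id); ``groups`` maps each sample to one of
    exactly two group labels with >= 2 samples each.  BH is applied across
    all features of this feature set, including features whose summed RPM is
    zero everywhere (those get p = 1), so the number of tests is fixed by
    the feature set alone.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    cols_a = [s for s in sample_feature_sums.columns if groups[s] == labels[0]]
    cols_b = [s for s in sample_feature_sums.columns if groups[s] == labels[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = sample_feature_sums[cols_a].to_numpy()
    b = sample_feature_sums[cols_b].to_numpy()
    ws = np.empty(len(sample_feature_sums))
    ps = np.empty(len(sample_feature_sums))
    for i in range(len(sample_feature_sums)):
        ws[i], ps[i] = wilcoxon_rank_sum(a[i], b[i])
    qs = bh_fdr(ps)
    iv = features.intervals.set_index("feature_id").loc[sample_feature_sums.index]
    return pd.DataFrame(
        {
            "feature_id": sample_feature_sums.index,
            "chrom": iv["chrom"].to_numpy(),
            "start": iv["start"].to_numpy(),
            "end": iv["end"].to_numpy(),
            f"mean_{labels[0]}": a.mean(axis=1),
            f"mean_{labels[1]}": b.mean(axis=1),
            "W": ws,
            "p_value": ps,
            "q_value": qs,
            "significant": qs <= fdr_cutoff,
        }
    ).reset_index(drop=True)
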