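"""Lane-level quality control for MBD-capture sequencing.

A MethylCap-seq experiment is only interpretable if methylated fragments
were actually enriched before sequencing; a capture failure turns the lane
into a near-uniform sample of the fragment pool.  Three metrics flag this:

* **CpG enrichment** — CpG frequency within the lane's extended fragments
  divided by the genome-wide CpG frequency (relative-frequency form).  A
  value near 1 means no enrichment.
* **Saturation** — Pearson correlation of genome-binned counts between two
  random halves of the lane's reads; a reproducibility proxy.
* **5x CpG coverage** — fraction of all genomic CpG sites overlapped by at
  least five deduplicated extended fragments.

A lane is excluded when any metric falls strictly below its threshold
(defaults 1.4 / 0.5 / 0.05); values exactly at a threshold pass.  A fourth
statistic, **noise**, is the percentage of uniquely aligned extended reads
whose bin contains no CpG — methylation signal there is biologically
implausible, so noise rises when capture fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import Lane, bin_counts, extend_fragments
from .genome_index import GenomeIndex

__all__ = [
    "QCThresholds",
    "QCReport",
    "cpg_enrichment",
    "saturation",
    "coverage_5x",
    "noise_pct",
    "average_noise_by_sample",
    "qc_classify",
    "qc_lane",
    "qc_table",
]


@dataclass(frozen=True)
class QCThresholds:
    min_enrichment: float = 1.4
    min_saturation: float = 0.5
    min_coverage5x: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_enrichment, self.min_saturation, self.min_coverage5x) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class QCReport:
    lane_id: str
    sample_id: str = ""
    cpg_enrichment: float = float("nan")
    saturation: float = float("nan")
    coverage5x: float = float("nan")
    noise_pct: float = float("nan")
    total_raw_reads: int = 0
    total_unique_aligned: int = 0
    passed: bool = False
    failed_criteria: list[str] = field(default_factory=list)
    seed: int | None = None
    force_included: bool = False


def cpg_enrichment(lane: Lane, index: GenomeIndex) -> float:
    """Ratio of the fragment-pool CpG frequency to the genome CpG frequency.

    Sample frequency is total CpG sites inside extended fragments divided by
    total extended-fragment length, counting overlapping fragments
    separately; genome frequency is total_cpg / total_length.
    """
    if index.total_cpg == 0:
        raise ValueError("reference genome contains no CpGs")
    cidx, a, b = extend_fragments(lane, index)
    total_len = int((b - a).sum())
    if total_len == 0:
        raise ValueError("lane has no extended-fragment territory")
    n_cpg = 0
    for ci, name in enumerate(lane.chrom_names):
        mask = cidx == ci
        if not mask.any():
            continue
        sites = index.cpg_sites[name]
        n_cpg += int(
            (np.searchsorted(sites, b[mask]) - np.searchsorted(sites, a[mask])).sum()
        )
    sample_freq = n_cpg / total_len
    genome_freq = index.total_cpg / index.total_length
    return float(sample_freq / genome_freq)


def _half_lane(lane: Lane, sel: np.ndarray) -> Lane:
    return Lane(
        sample_id=lane.sample_id,
        lane_id=lane.lane_id,
        library_id=lane.library_id,
        chrom_names=lane.chrom_names,
        chrom_idx=lane.chrom_idx[sel],
        start=lane.start[sel],
        strand=lane.strand[sel],
        read_length=lane.read_length[sel],
        total_raw_reads=lane.total_raw_reads,
        fragment_length=lane.fragment_length,
    )


def saturation(lane: Lane, index: GenomeIndex, seed: int) -> float:
    """Pearson r between binned counts of two random halves of the lane.

    The split is a seeded permutation; with an odd read count the first half
    gets the extra read.  If a half has no count variance across bins the
    correlation is undefined: elementwise-proportional halves return the
    limit 1.0, anything else raises a "degenerate partition" error.
    """
    n = lane.total_unique_aligned
    if n < 2:
        raise ValueError("saturation needs at least 2 reads")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = -(-n // 2)
    v1 = bin_counts(_half_lane(lane, perm[:k]), index).counts.astype(float)
    v2 = bin_counts(_half_lane(lane, perm[k:]), index).counts.astype(float)
    if v1.std() == 0 or v2.std() == 0:
        s1, s2 = v1.sum(), v2.sum()
        if s1 > 0 and s2 > 0 and np.allclose(v1 / s1, v2 / s2):
            return 1.0
        raise ValueError("degenerate partition: a half has constant bin counts")
    return float(np.corrcoef(v1, v2)[0, 1])


def coverage_5x(lane: Lane, index: GenomeIndex, depth_threshold: int = 5) -> float:
    """Fraction of genomic CpG sites covered by >= depth_threshold extended
    fragments (a site is covered when its C lies inside the fragment)."""
    if index.total_cpg == 0:
        raise ValueError("reference genome contains no CpGs")
    cidx, a, b = extend_fragments(lane, index)
    covered = 0
    for ci, name in enumerate(lane.chrom_names):
        sites = index.cpg_sites[name]
        if sites.size == 0:
            continue
        mask = cidx == ci
        starts = np.sort(a[mask])
        ends = np.sort(b[mask])
        # depth at site p = #fragments with a <= p minus #fragments with b <= p
        depth = np.searchsorted(starts, sites, side="right") - np.searchsorted(
            ends, sites, side="right"
        )
        covered += int(np.count_nonzero(depth >= depth_threshold))
    return float(covered / index.total_cpg)


def noise_pct(lane: Lane, index: GenomeIndex) -> float:
    """Percentage of the lane's reads assigned to bins with zero CpGs."""
    bv = bin_counts(lane, index)
    zero_mask = index.all_bin_cpg_counts == 0
    return float(100.0 * bv.counts[zero_mask].sum() / bv.total_assigned)


def average_noise_by_sample(reports: list[QCReport]) -> pd.DataFrame:
    """Mean lane noise per (sample, QC status) group.

    A sample with both passing and failing lanes appears once per status.
    """
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "status": ["pass" if r.passed else "fail" for r in reports],
            "noise_pct": [r.noise_pct for r in reports],
        }
    )
    return (
        df.groupby(["sample_id", "status"], sort=True)["noise_pct"]
        .mean()
        .reset_index()
    )


def qc_classify(report: QCReport, thresholds: QCThresholds) -> QCReport:
    """Apply exclusion thresholds: fail iff any metric is strictly below its
    threshold; equality passes.  Fills ``passed`` and ``failed_criteria``."""
    for name, value in (
        ("cpg_enrichment", report.cpg_enrichment),
        ("saturation", report.saturation),
        ("coverage5x", report.coverage5x),
    ):
        if not np.isfinite(value):
            raise ValueError(f"missing QC metric: {name}")
    failed = []
    if report.cpg_enrichment < thresholds.min_enrichment:
        failed.append("cpg_enrichment")
    if report.saturation < thresholds.min_saturation:
        failed.append("saturation")
    if report.coverage5x < thresholds.min_coverage5x:
        failed.append("coverage5x")
    report.failed_criteria = failed
    report.passed = not failed or report.force_included
    return report


def qc_lane(
    lane: Lane,
    index: GenomeIndex,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
    force_include: bool = False,
) -> QCReport:
    """Compute all four statistics for one lane and classify it.

    ``force_include`` mirrors a manual QC override: the metrics and the
    failed criteria are still recorded, but the lane is kept.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport(
        lane_id=lane.lane_id,
        sample_id=lane.sample_id,
        cpg_enrichment=cpg_enrichment(lane, index),
        saturation=saturation(lane, index, seed=seed),
        coverage5x=coverage_5x(lane, index),
        noise_pct=noise_pct(lane, index),
        total_raw_reads=lane.total_raw_reads,
        total_unique_aligned=lane.total_unique_aligned,
        seed=seed,
        force_included=force_include,
    )
    return qc_classify(report, thresholds)


def qc_table(reports: list[QCReport]) -> pd.DataFrame:
    """One row per lane: metrics, reads, noise, verdict."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "lane_id": [r.lane_id for r in reports],
            "cpg_enrichment": [r.cpg_enrichment for r in reports],
            "saturation": [r.saturation for r in reports],
            "coverage5x": [r.coverage5x for r in reports],
            "noise_pct": [r.noise_pct for r in reports],
            "total_raw_reads": [r.total_raw_reads for r in reports],
            "total_unique_aligned": [r.total_unique_aligned for r in reports],
            "verdict": ["pass" if r.passed else "fail" for r in reports],
            "failed_criteria": [
                ",".join(r.failed_criteria) for r in reports
            ],
        }
    )
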