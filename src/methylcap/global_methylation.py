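"""Global methylation indicator (GMI) and spike-in validation.

Because MethylCap-seq signal is normalized to reads per million, two samples
with identically *distributed* methylation but different absolute levels
produce identical profiles — the total read count is set by the sequencer,
not by how methylated the sample is.  The GMI recovers a relative global
signal from the *shape* of the profile: normalized bin counts are stratified
by the CpG density of the bin (CpG count per 500-bp bin, pooled above a
ceiling class), the mean RPM per density class forms a methylation
distribution, and the GMI is the area under that curve (unit-width sum of
class means).  Globally hypermethylated samples shift read mass into
CpG-dense bins, which raises the means of the sparse high-density classes
and hence the GMI.

The orthogonal wet-lab check is a fully methylated plasmid spiked into the
genomic DNA at fixed concentration before capture.  The plasmid competes
with natively methylated fragments for MBD binding, so its post-capture
read share moves inversely with the sample's global methylation; GMI is
validated by regressing it on the inverse of the plasmid's reads per
million of *raw* reads (duplicates retained, unlike the genomic analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .alignment_io import BinCountVector
from .genome_index import GenomeIndex

__all__ = [
    "MethylationDistribution",
    "SpikeInRecord",
    "RegressionResult",
    "methylation_distribution",
    "gmi",
    "count_spikein_reads",
    "gmi_spikein_regression",
]

DEFAULT_C_MAX = 25

_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


@dataclass
class MethylationDistribution:
    """Mean RPM per CpG-density class and its AUC (the GMI)."""

    table: pd.DataFrame  # columns: cpg_class, n_bins, mean_rpm
    gmi: float
    c_max: int


def methylation_distribution(
    sample_bins: BinCountVector, index: GenomeIndex, c_max: int = DEFAULT_C_MAX
) -> MethylationDistribution:
    """Stratify bin RPM by per-bin CpG count and average within classes.

    Zero-CpG bins are excluded — they are the noise domain, and including
    them would let enrichment failures inflate the indicator.  Class means
    are taken over every grid bin in the class, zero-RPM bins included;
    classes with no bins in this genome are dropped from the table.  The GMI
    is the unit-width sum of the class means.
    """
    if sample_bins.rpm is None:
        raise ValueError("sample bins must be RPM-normalized")
    density = index.all_bin_cpg_counts
    keep = density >= 1
    if not keep.any():
        raise ValueError("genome has no bins containing a CpG")
    classes = np.minimum(density[keep], c_max)
    rpm = sample_bins.rpm[keep]
    n_bins = np.bincount(classes, minlength=c_max + 1)[1:]
    sums = np.bincount(classes, weights=rpm, minlength=c_max + 1)[1:]
    present = n_bins > 0
    means = np.zeros_like(sums)
    means[present] = sums[present] / n_bins[present]
    table = pd.DataFrame(
        {
            "cpg_class": np.arange(1, c_max + 1)[present],
            "n_bins": n_bins[present],
            "mean_rpm": means[present],
        }
    )
    return MethylationDistribution(
        table=table, gmi=float(means[present].sum()), c_max=c_max
    )


def gmi(
    sample_bins: BinCountVector, index: GenomeIndex, c_max: int = DEFAULT_C_MAX
) -> float:
    """Area under the CpG-density methylation distribution."""
    return methylation_distribution(sample_bins, index, c_max=c_max).gmi


@dataclass
class SpikeInRecord:
    sample_id: str
    construct_name: str
    construct_read_count: int
    total_raw_reads: int
    gmi: float = float("nan")

    @property
    def construct_rpm(self) -> float:
        """Construct reads per million of the lane's total raw reads."""
        return self.construct_read_count * 1e6 / self.total_raw_reads


def count_spikein_reads(
    sam_path: str,
    construct_name: str,
    total_raw_reads: int,
    sample_id: str = "",
) -> SpikeInRecord:
    """Count primary alignments to the spike-in construct, duplicates kept.

    PCR duplicates are retained here (unlike the genomic workflow) because
    the construct is a single short template: genuinely independent capture
    events frequently share coordinates.  Raises if the construct is not an
    alignment target of the file.
    """
    count = 0
    seen_targets: set[str] = set()
    with open(sam_path) as fh:
        has_header = fh.readline().startswith("@")
    if has_header:
        with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
            seen_targets.update(sam.references)
            for rec in sam:
                if rec.flag & (_FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                    continue
                if rec.reference_name == construct_name:
                    count += 1
    else:
        with open(sam_path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) < 10:
                    continue
                flag = int(f[1])
                if flag & (_FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                    continue
                seen_targets.add(f[2])
                if f[2] == construct_name:
                    count += 1
    if construct_name not in seen_targets:
        raise ValueError(
            f"construct {construct_name!r} is not an alignment target of {sam_path}"
        )
    return SpikeInRecord(
        sample_id=sample_id,
        construct_name=construct_name,
        construct_read_count=count,
        total_raw_reads=total_raw_reads,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def gmi_spikein_regression(records: list[SpikeInRecord]) -> RegressionResult:
    """OLS of GMI on inverse construct RPM across samples.

    p is the two-sided t test on the slope (df = n - 2).  Requires n >= 3,
    positive construct RPM everywhere and nonconstant 1/RPM.
    """
    if len(records) < 3:
        raise ValueError("regression needs at least 3 samples")
    rpm = np.array([r.construct_rpm for r in records], dtype=float)
    if np.any(rpm <= 0):
        raise ValueError("all construct RPM values must be positive")
    x = 1.0 / rpm
    y = np.array([r.gmi for r in records], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("inverse construct RPM has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(records),
    )
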