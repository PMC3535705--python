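"""Per-lane alignment loading, deduplication, fragment extension and binning.

The assay is 36-bp single-ended sequencing of MBD-captured fragments, so a
read is only the 5' tip of the fragment that was actually captured.  Reads
are therefore extended to the average fragment length (default 150 bp,
overridable per lane in the manifest), deduplicated on (chrom, position,
strand) to remove PCR artefacts, counted into the genome-wide 500-bp bin
grid, and normalized to reads per million (RPM) of the lane's uniquely
aligned reads.  Replicate lanes of a sample are normalized first and then
averaged, so the merged profile still sums to 10^6 RPM.

Each extended fragment is assigned to exactly one bin — the bin containing
its midpoint — which keeps bin counts an exact partition of the lane's reads.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome_index import GenomeIndex

__all__ = [
    "AlignedRead",
    "Lane",
    "BinCountVector",
    "ManifestEntry",
    "read_manifest",
    "load_alignments",
    "extend_read",
    "extend_fragments",
    "bin_counts",
    "rpm_normalize",
    "merge_replicate_lanes",
    "write_bedgraph",
]

DEFAULT_FRAGMENT_LENGTH = 150

# SAM FLAG bits
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely aligned single-end read."""

    chrom: str
    start: int  # 0-based leftmost aligned position
    strand: str  # '+' or '-'
    read_length: int


@dataclass
class Lane:
    """One sequencing lane after duplicate-alignment removal.

    Reads are stored as parallel arrays for vectorized downstream work;
    ``chrom_idx`` indexes into ``chrom_names``.
    """

    sample_id: str
    lane_id: str
    library_id: str
    chrom_names: list[str]
    chrom_idx: np.ndarray  # int32
    start: np.ndarray  # int64
    strand: np.ndarray  # int8: 0 = '+', 1 = '-'
    read_length: np.ndarray  # int32
    total_raw_reads: int
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH

    @property
    def total_unique_aligned(self) -> int:
        return int(self.start.size)

    def reads(self) -> list[AlignedRead]:
        """Materialize reads as :class:`AlignedRead` objects (small lanes)."""
        return [
            AlignedRead(
                self.chrom_names[c], int(s), "-" if v else "+", int(rl)
            )
            for c, s, v, rl in zip(
                self.chrom_idx, self.start, self.strand, self.read_length
            )
        ]


@dataclass
class ManifestEntry:
    sample_id: str
    lane_id: str
    library_id: str
    path: str
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    total_raw_reads: int | None = None
    group: str = ""


MANIFEST_COLUMNS = [
    "sample_id",
    "lane_id",
    "library_id",
    "path",
    "fragment_length",
    "total_raw_reads",
    "group",
]


def read_manifest(path: str) -> list[ManifestEntry]:
    """Read the tab-delimited sample→lane→group manifest."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    for row in df.itertuples(index=False):
        p = row.path
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        raw = row.total_raw_reads
        entries.append(
            ManifestEntry(
                sample_id=row.sample_id,
                lane_id=row.lane_id,
                library_id=row.library_id,
                path=p,
                fragment_length=int(row.fragment_length),
                total_raw_reads=None if pd.isna(raw) or raw == "" else int(raw),
                group="" if pd.isna(row.group) else row.group,
            )
        )
    return entries


def _dedup(chrom_idx, start, strand, read_length):
    """Keep the first read for each (chrom, position, strand)."""
    df = pd.DataFrame(
        {"c": chrom_idx, "s": start, "v": strand, "l": read_length}
    )
    keep = ~df.duplicated(subset=["c", "s", "v"], keep="first")
    df = df[keep.to_numpy()]
    return (
        df["c"].to_numpy(np.int32),
        df["s"].to_numpy(np.int64),
        df["v"].to_numpy(np.int8),
        df["l"].to_numpy(np.int32),
    )


def _parse_sam(path: str, index: GenomeIndex | None, skip_contigs: frozenset[str]):
    """Parse a SAM file into raw read arrays plus the raw record count.

    pysam handles files with a header; a headerless minimal dialect
    (QNAME FLAG RNAME POS ... SEQ) is parsed directly.
    """
    with open(path) as fh:
        first = fh.readline()
    chrom_idx, start, strand, rlen = [], [], [], []
    n_raw = 0
    known = set(index.chrom_names) if index is not None else None

    def handle(flag: int, rname: str, pos0: int, seq_len: int):
        nonlocal n_raw
        n_raw += 1
        if flag & (_FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
            return
        if rname in skip_contigs:
            return
        if known is not None and rname not in known:
            raise ValueError(f"contig not in genome index: {rname}")
        chrom_idx.append(rname)
        start.append(pos0)
        strand.append(1 if flag & _FLAG_REVERSE else 0)
        rlen.append(seq_len)

    if first.startswith("@"):
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam:
                if rec.flag & (_FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                    n_raw += 0  # secondary records are not extra raw reads
                    continue
                if rec.is_unmapped:
                    n_raw += 1
                    continue
                seq_len = rec.query_length or rec.infer_query_length() or 0
                handle(rec.flag, rec.reference_name, rec.reference_start, seq_len)
    else:
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) < 10:
                    continue
                flag, rname, pos = int(f[1]), f[2], int(f[3])
                seq = f[9]
                handle(flag, rname, pos - 1, len(seq) if seq != "*" else 0)
    return chrom_idx, start, strand, rlen, n_raw


def load_alignments(
    path: str,
    entry: ManifestEntry,
    index: GenomeIndex,
    skip_contigs: tuple[str, ...] = (),
) -> Lane:
    """Load one lane from SAM or BED6, dropping unmapped/secondary records
    and duplicate alignments.

    ``skip_contigs`` names contigs (e.g. a spike-in construct) whose records
    are excluded from the genomic analysis; any other contig absent from the
    index raises.  For BED input ``total_raw_reads`` comes from the manifest
    (BED has no unmapped records); for SAM it is counted from the file unless
    the manifest overrides it.
    """
    skip = frozenset(skip_contigs)
    if path.endswith((".bed", ".bed6")):
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        )
        bed = bed[~bed["chrom"].isin(skip)]
        unknown = set(bed["chrom"]) - set(index.chrom_names)
        if unknown:
            raise ValueError(f"contig not in genome index: {sorted(unknown)[0]}")
        names = bed["chrom"].tolist()
        starts = bed["start"].to_numpy(np.int64)
        strands = (bed["strand"] == "-").to_numpy(np.int8)
        rlens = (bed["end"] - bed["start"]).to_numpy(np.int32)
        n_raw = entry.total_raw_reads if entry.total_raw_reads else len(bed)
    else:
        names, s, v, l, n_counted = _parse_sam(path, index, skip)
        starts = np.asarray(s, dtype=np.int64)
        strands = np.asarray(v, dtype=np.int8)
        rlens = np.asarray(l, dtype=np.int32)
        n_raw = entry.total_raw_reads if entry.total_raw_reads else n_counted

    if len(names) == 0:
        raise ValueError(f"no usable reads in {path}")

    name_to_idx = {c: i for i, c in enumerate(index.chrom_names)}
    cidx = np.fromiter((name_to_idx[c] for c in names), dtype=np.int32, count=len(names))
    cidx, starts, strands, rlens = _dedup(cidx, starts, strands, rlens)
    return Lane(
        sample_id=entry.sample_id,
        lane_id=entry.lane_id,
        library_id=entry.library_id,
        chrom_names=list(index.chrom_names),
        chrom_idx=cidx,
        start=starts,
        strand=strands,
        read_length=rlens,
        total_raw_reads=int(n_raw),
        fragment_length=entry.fragment_length,
    )


def extend_read(
    read: AlignedRead, fragment_length: int, index: GenomeIndex
) -> tuple[int, int]:
    """Extend a read to the fragment it represents; clip to the contig.

    A + strand read grows 3'-ward from its start; a − strand read covers the
    rightmost ``read_length`` bases of its fragment, so the fragment grows
    leftward from the read's end.
    """
    if fragment_length < read.read_length:
        raise ValueError("fragment_length must be >= read_length")
    chrom_len = index.chrom_lengths[read.chrom]
    if read.strand == "+":
        a, b = read.start, read.start + fragment_length
    else:
        end = read.start + read.read_length
        a, b = end - fragment_length, end
    return max(a, 0), min(b, chrom_len)


def extend_fragments(lane: Lane, index: GenomeIndex):
    """Vectorized fragment extension for every read in a lane.

    Returns (chrom_idx, frag_start, frag_end) arrays, clipped to contigs.
    """
    L = lane.fragment_length
    lengths = np.array(
        [index.chrom_lengths[c] for c in lane.chrom_names], dtype=np.int64
    )
    clen = lengths[lane.chrom_idx]
    plus = lane.strand == 0
    a = np.where(plus, lane.start, lane.start + lane.read_length - L)
    b = np.where(plus, lane.start + L, lane.start + lane.read_length)
    return lane.chrom_idx, np.clip(a, 0, clen), np.clip(b, 0, clen)


@dataclass
class BinCountVector:
    """Read counts (and optionally RPM) over the whole concatenated grid."""

    counts: np.ndarray
    total_assigned: int
    rpm: np.ndarray | None = None
    bin_size: int = 500
    chrom_names: list[str] = field(default_factory=list)
    n_bins_per_chrom: dict[str, int] = field(default_factory=dict)


def bin_counts(lane: Lane, index: GenomeIndex) -> BinCountVector:
    """Count extended fragments into the bin grid by fragment midpoint.

    Midpoint of the half-open interval [a, b) is floor((a + b - 1) / 2); the
    fragment contributes to exactly the bin containing that base, so
    ``sum(counts) == lane.total_unique_aligned``.
    """
    cidx, a, b = extend_fragments(lane, index)
    mid = (a + b - 1) // 2
    offsets = index.bin_offsets
    off = np.array([offsets[c] for c in index.chrom_names], dtype=np.int64)
    gbin = off[cidx] + mid // index.bin_size
    counts = np.bincount(gbin, minlength=index.total_bins).astype(np.int64)
    return BinCountVector(
        counts=counts,
        total_assigned=int(counts.sum()),
        bin_size=index.bin_size,
        chrom_names=list(index.chrom_names),
        n_bins_per_chrom={c: index.n_bins(c) for c in index.chrom_names},
    )


def rpm_normalize(bins: BinCountVector) -> BinCountVector:
    """Scale counts to reads per million of the lane's assigned reads."""
    if bins.total_assigned <= 0:
        raise ValueError("cannot RPM-normalize a lane with zero assigned reads")
    rpm = bins.counts * (1e6 / bins.total_assigned)
    return BinCountVector(
        counts=bins.counts,
        total_assigned=bins.total_assigned,
        rpm=rpm,
        bin_size=bins.bin_size,
        chrom_names=bins.chrom_names,
        n_bins_per_chrom=bins.n_bins_per_chrom,
    )


def merge_replicate_lanes(lanes: list[BinCountVector]) -> BinCountVector:
    """Average replicate lanes' RPM vectors (normalize-then-average)."""
    if not lanes:
        raise ValueError("no lanes to merge")
    n = lanes[0].counts.size
    for lv in lanes:
        if lv.counts.size != n or lv.bin_size != lanes[0].bin_size:
            raise ValueError("lanes are on different bin grids")
        if lv.rpm is None:
            raise ValueError("lanes must be RPM-normalized before merging")
    rpm = np.mean([lv.rpm for lv in lanes], axis=0)
    counts = np.sum([lv.counts for lv in lanes], axis=0)
    return BinCountVector(
        counts=counts,
        total_assigned=int(sum(lv.total_assigned for lv in lanes)),
        rpm=rpm,
        bin_size=lanes[0].bin_size,
        chrom_names=lanes[0].chrom_names,
        n_bins_per_chrom=lanes[0].n_bins_per_chrom,
    )


def write_bedgraph(bins: BinCountVector, index: GenomeIndex, path: str,
                   use_rpm: bool = True) -> None:
    """Write per-bin counts or RPM as bedGraph (zero bins omitted)."""
    values = bins.rpm if (use_rpm and bins.rpm is not None) else bins.counts
    offsets = index.bin_offsets
    with open(path, "w") as fh:
        for c in index.chrom_names:
            off = offsets[c]
            nb = index.n_bins(c)
            length = index.chrom_lengths[c]
            vals = values[off : off + nb]
            for i in np.flatnonzero(vals):
                start = i * index.bin_size
                end = min(start + index.bin_size, length)
                fh.write(f"{c}\t{start}\t{end}\t{vals[i]:.6g}\n")
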