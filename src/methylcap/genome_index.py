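"""Reference genome structures for binned methylation analysis.

A :class:`GenomeIndex` holds, per contig, the chromosome length, the sorted
0-based positions of every CpG dinucleotide (the position of the C on the
forward strand), and a fixed-width bin grid (default 500 bp) annotated with
the number of CpG sites falling in each bin.  Every downstream computation —
read binning, the CpG-enrichment QC score, zero-CpG "noise" bins, CpG-density
classes for the global methylation indicator — is defined against this index.

Coordinates are 0-based, half-open throughout; bin ``i`` of a contig spans
``[i * bin_size, (i + 1) * bin_size)`` and a CpG belongs to the bin containing
its C.  Soft-masked (lowercase) bases are treated as ordinary bases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeIndex",
    "build_genome_index",
    "build_genome_index_from_sequences",
    "find_cpg_sites",
    "zero_cpg_bin_fraction",
]

DEFAULT_BIN_SIZE = 500


def find_cpg_sites(sequence: str) -> np.ndarray:
    """Return sorted 0-based positions of the C of every CG dinucleotide.

    Case-insensitive; ambiguous bases (N etc.) never form CpGs because the
    comparison is against the literal characters C and G.
    """
    if len(sequence) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    return hits.astype(np.int64)


@dataclass
class GenomeIndex:
    """Chromosome sizes, CpG coordinates and the CpG-annotated bin grid."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cpg_sites: dict[str, np.ndarray]
    bin_size: int = DEFAULT_BIN_SIZE
    bin_cpg_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bin_cpg_counts:
            for name in self.chrom_names:
                nb = self.n_bins(name)
                sites = self.cpg_sites[name]
                self.bin_cpg_counts[name] = np.bincount(
                    sites // self.bin_size, minlength=nb
                ).astype(np.int64)

    # -- grid geometry -----------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)  # ceil div

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    @property
    def bin_offsets(self) -> dict[str, int]:
        """First global-grid bin index of each contig (contigs concatenated
        in ``chrom_names`` order)."""
        off, out = 0, {}
        for c in self.chrom_names:
            out[c] = off
            off += self.n_bins(c)
        return out

    @property
    def all_bin_cpg_counts(self) -> np.ndarray:
        """Per-bin CpG counts over the whole (concatenated) grid."""
        return np.concatenate(
            [self.bin_cpg_counts[c] for c in self.chrom_names]
        )

    # -- totals ------------------------------------------------------------

    @property
    def total_cpg(self) -> int:
        return int(sum(len(self.cpg_sites[c]) for c in self.chrom_names))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    # -- persistence -------------------------------------------------------

    def save(self, directory: str) -> None:
        """Persist as documented tab-delimited sidecars.

        ``chroms.tsv``  : contig, length, bin_size
        ``cpg_sites.tsv``: contig, 0-based position of the C
        """
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "chroms.tsv"), "w") as fh:
            fh.write("chrom\tlength\tbin_size\n")
            for c in self.chrom_names:
                fh.write(f"{c}\t{self.chrom_lengths[c]}\t{self.bin_size}\n")
        with open(os.path.join(directory, "cpg_sites.tsv"), "w") as fh:
            fh.write("chrom\tpos\n")
            for c in self.chrom_names:
                for p in self.cpg_sites[c]:
                    fh.write(f"{c}\t{p}\n")

    @classmethod
    def load(cls, directory: str) -> "GenomeIndex":
        names: list[str] = []
        lengths: dict[str, int] = {}
        bin_size = DEFAULT_BIN_SIZE
        with open(os.path.join(directory, "chroms.tsv")) as fh:
            next(fh)
            for line in fh:
                c, ln, bs = line.rstrip("\n").split("\t")
                names.append(c)
                lengths[c] = int(ln)
                bin_size = int(bs)
        sites: dict[str, list[int]] = {c: [] for c in names}
        with open(os.path.join(directory, "cpg_sites.tsv")) as fh:
            next(fh)
            for line in fh:
                c, p = line.rstrip("\n").split("\t")
                sites[c].append(int(p))
        return cls(
            chrom_names=names,
            chrom_lengths=lengths,
            cpg_sites={c: np.asarray(v, dtype=np.int64) for c, v in sites.items()},
            bin_size=bin_size,
        )

    def to_bed4(self, path: str) -> None:
        """Export per-bin CpG counts as BED4 (chrom, start, end, cpg_count)."""
        with open(path, "w") as fh:
            for c in self.chrom_names:
                counts = self.bin_cpg_counts[c]
                length = self.chrom_lengths[c]
                for i, n in enumerate(counts):
                    start = i * self.bin_size
                    end = min(start + self.bin_size, length)
                    fh.write(f"{c}\t{start}\t{end}\t{int(n)}\n")


def build_genome_index_from_sequences(
    sequences: dict[str, str], bin_size: int = DEFAULT_BIN_SIZE
) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from in-memory contig sequences."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if not sequences:
        raise ValueError("no contigs provided")
    names = list(sequences)
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names")
    lengths = {c: len(s) for c, s in sequences.items()}
    sites = {c: find_cpg_sites(s) for c, s in sequences.items()}
    return GenomeIndex(
        chrom_names=names, chrom_lengths=lengths, cpg_sites=sites, bin_size=bin_size
    )


def build_genome_index(fasta: str, bin_size: int = DEFAULT_BIN_SIZE) -> GenomeIndex:
    """Scan a (multi-contig) FASTA and build the CpG/bin index.

    Raises on an empty FASTA or duplicate contig names.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(fasta, "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate contig name: {rec.id}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise ValueError(f"empty FASTA: {fasta}")
    return build_genome_index_from_sequences(sequences, bin_size=bin_size)


def zero_cpg_bin_fraction(index: GenomeIndex) -> float:
    """Fraction of grid bins containing no CpG dinucleotide.

    These CpG-barren bins are the domain of the noise statistic: reads
    assigned there cannot reflect CpG methylation.
    """
    counts = index.all_bin_cpg_counts
    return float(np.count_nonzero(counts == 0) / counts.size)
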