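"""Synthetic MBD-capture experiments with known truth.

The simulator emulates what matters to the analysis stack, not sequencing
chemistry: a small genome with CpG-dense islands, CpG-sparse background and
a CpG-free territory; region-level methylation states; capture sampling in
which a fragment's selection weight grows linearly with the number of
methylated CpGs it carries (weight = 1 + k * mCpG); PCR duplicates injected
by resampling emitted reads; an enrichment-failure mode that samples
fragments uniformly (also used for input lanes); and a fully methylated
spike-in construct that competes for capture inside the same weighted draw,
at a fixed copy number per genome.

Every draw flows from a single ``numpy`` Generator, so (config, seed) is a
pure function of the outputs, and each lane carries a truth log from which
downstream expectations (dedup counts, construct read share, noise mass)
can be recomputed directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import alignment_io
from .alignment_io import Lane, ManifestEntry
from .dmr import FeatureSet
from .genome_index import GenomeIndex, build_genome_index_from_sequences

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "MethylationTruth",
    "SimulatedLane",
    "SampleSpec",
    "CohortSim",
    "simulate_genome",
    "draw_methylation",
    "simulate_lane",
    "simulate_cohort",
    "island_featureset",
]

GENOME_CHROM = "chr1"
CONSTRUCT_NAME = "spike_construct"
BACKGROUND_CHUNK = 1000  # bp; methylation-state region size outside islands


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale defaults: a 2 Mb genome and 100k reads per lane keep every
    end-to-end property affordable while leaving thousands of bins."""

    seed: int = 0
    genome_length: int = 2_000_000
    n_islands: int = 200
    island_length: int = 1_000
    island_cpg_rate: float = 0.08  # CpG per bp inside islands
    background_cpg_rate: float = 0.008  # roughly genomic CpG density
    zero_cpg_fraction: float = 0.10  # CpG-free territory (noise domain)
    methylation_level: float = 0.5  # P(region methylated)
    capture_strength: float = 1.0  # k in weight = 1 + k * mCpG; 0 = failed
    fragment_length: int = 150
    read_length: int = 36
    reads_per_lane: int = 100_000
    duplicate_rate: float = 0.05
    spikein_copies_per_genome: float = 2.5
    construct_length: int = 5_300
    construct_cpg_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("zero_cpg_fraction", "methylation_level", "duplicate_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1 or (name == "duplicate_rate" and v >= 1):
                raise ValueError(f"{name} out of range: {v}")
        if self.capture_strength < 0 or self.spikein_copies_per_genome < 0:
            raise ValueError("capture_strength and spike-in copies must be >= 0")
        if self.n_islands * self.island_length > self.genome_length * (
            1 - self.zero_cpg_fraction
        ):
            raise ValueError("island territory exceeds the CpG-bearing genome")


def _plant_sites(rng, start: int, end: int, rate: float) -> np.ndarray:
    """CpG C-positions in [start, end-1) on an even-offset lattice, so no
    two planted CpGs overlap; per-bp density matches ``rate``."""
    candidates = np.arange(start, end - 1, 2)
    keep = rng.random(candidates.size) < min(rate * 2, 1.0)
    return candidates[keep]


@dataclass
class SimulatedGenome:
    config: SimConfig
    sequence: str
    islands: list[tuple[int, int]]
    cpg_sites: np.ndarray  # genome-wide, sorted
    island_of_site: np.ndarray  # island index per site, -1 for background
    bg_chunk_of_site: np.ndarray  # background chunk id per site, -1 in islands
    construct_sequence: str
    construct_cpg_sites: np.ndarray
    zero_cpg_start: int  # CpG-free territory is [zero_cpg_start, genome_length)

    @property
    def n_bg_chunks(self) -> int:
        return int(self.bg_chunk_of_site.max()) + 1 if self.bg_chunk_of_site.size else 0

    def write_fasta(self, path: str, include_construct: bool = False, width: int = 80):
        with open(path, "w") as fh:
            for name, seq in [(GENOME_CHROM, self.sequence)] + (
                [(CONSTRUCT_NAME, self.construct_sequence)] if include_construct else []
            ):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def build_index(self, bin_size: int = 500) -> GenomeIndex:
        return build_genome_index_from_sequences(
            {GENOME_CHROM: self.sequence}, bin_size=bin_size
        )


def _random_backbone(rng, length: int) -> np.ndarray:
    """Random ACGT bytes with every natural CG dinucleotide destroyed, so
    the planted CpGs are exactly the genome's CpGs (exact truth)."""
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
    cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    arr[cg + 1] = ord("T")
    return arr


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Deterministically build the three-strata genome and the construct."""
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    zero_start = G - int(round(G * config.zero_cpg_fraction))

    arr = _random_backbone(rng, G)

    # islands: one per equal segment of the CpG-bearing territory, at a
    # random offset inside its segment -> non-overlapping by construction
    seg = zero_start // config.n_islands
    islands = []
    for i in range(config.n_islands):
        off = int(rng.integers(0, max(seg - config.island_length, 1)))
        s = i * seg + off
        islands.append((s, s + config.island_length))

    sites, island_of, chunk_of = [], [], []
    prev_end = 0
    for gi, (s, e) in enumerate(islands + [(zero_start, zero_start)]):
        bg = _plant_sites(rng, prev_end, s, config.background_cpg_rate)
        sites.append(bg)
        island_of.append(np.full(bg.size, -1, dtype=np.int64))
        chunk_of.append(bg // BACKGROUND_CHUNK)
        if gi < len(islands):
            isl = _plant_sites(rng, s, e, config.island_cpg_rate)
            sites.append(isl)
            island_of.append(np.full(isl.size, gi, dtype=np.int64))
            chunk_of.append(np.full(isl.size, -1, dtype=np.int64))
        prev_end = e
    cpg_sites = np.concatenate(sites)
    island_of_site = np.concatenate(island_of)
    bg_chunk_of_site = np.concatenate(chunk_of)

    for p in cpg_sites:
        arr[p] = ord("C")
        arr[p + 1] = ord("G")
    # re-destroy any CG formed at a planting boundary is impossible by
    # construction (C at p, G at p+1 cannot pair with neighbours into CG)

    c_arr = _random_backbone(rng, config.construct_length)
    c_sites = _plant_sites(rng, 0, config.construct_length, config.construct_cpg_rate)
    for p in c_sites:
        c_arr[p] = ord("C")
        c_arr[p + 1] = ord("G")

    return SimulatedGenome(
        config=config,
        sequence=arr.tobytes().decode("ascii"),
        islands=islands,
        cpg_sites=cpg_sites,
        island_of_site=island_of_site,
        bg_chunk_of_site=bg_chunk_of_site,
        construct_sequence=c_arr.tobytes().decode("ascii"),
        construct_cpg_sites=c_sites,
        zero_cpg_start=zero_start,
    )


@dataclass
class MethylationTruth:
    """One sample's region-level methylation states and the resulting set
    of methylated CpG positions."""

    island_state: np.ndarray  # bool per island
    bg_chunk_state: np.ndarray  # bool per background chunk
    methylated_sites: np.ndarray  # sorted positions
    level: float


def draw_methylation(
    genome: SimulatedGenome,
    level: float,
    rng: np.random.Generator,
    island_probs: np.ndarray | None = None,
) -> MethylationTruth:
    """Draw per-region methylation states.

    Islands and 1-kb background chunks each flip methylated with probability
    ``level`` (or a per-island probability override, used to plant true
    differential regions in cohorts); all CpGs of a region share its state.
    """
    n_isl = len(genome.islands)
    probs = np.full(n_isl, level) if island_probs is None else np.asarray(island_probs)
    island_state = rng.random(n_isl) < probs
    n_chunks = genome.n_bg_chunks
    bg_state = rng.random(n_chunks) < level
    is_island = genome.island_of_site >= 0
    meth = np.zeros(genome.cpg_sites.size, dtype=bool)
    meth[is_island] = island_state[genome.island_of_site[is_island]]
    meth[~is_island] = bg_state[genome.bg_chunk_of_site[~is_island]]
    return MethylationTruth(
        island_state=island_state,
        bg_chunk_state=bg_state,
        methylated_sites=genome.cpg_sites[meth],
        level=level,
    )


@dataclass
class SimulatedLane:
    """Emitted reads for one lane plus the truth needed to audit them."""

    sample_id: str
    lane_id: str
    library_id: str
    mode: str  # captured | failed | input
    genome: SimulatedGenome
    is_construct: np.ndarray  # per read
    read_start: np.ndarray
    strand: np.ndarray  # 0 = '+', 1 = '-'
    read_length: int
    n_duplicates_injected: int
    truth: dict = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return int(self.read_start.size)

    @property
    def construct_read_count(self) -> int:
        return int(self.is_construct.sum())

    def to_sam(self, path: str) -> None:
        g = self.genome
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{GENOME_CHROM}\tLN:{len(g.sequence)}\n")
            fh.write(f"@SQ\tSN:{CONSTRUCT_NAME}\tLN:{len(g.construct_sequence)}\n")
            rl = self.read_length
            for i in range(self.n_reads):
                rname = CONSTRUCT_NAME if self.is_construct[i] else GENOME_CHROM
                seq_src = g.construct_sequence if self.is_construct[i] else g.sequence
                s = int(self.read_start[i])
                flag = 16 if self.strand[i] else 0
                fh.write(
                    f"{self.lane_id}.{i}\t{flag}\t{rname}\t{s + 1}\t255\t{rl}M\t*\t0\t0\t"
                    f"{seq_src[s : s + rl]}\t*\n"
                )

    def to_lane(self, index: GenomeIndex) -> Lane:
        """Fast in-memory path to a deduplicated genomic :class:`Lane`
        (construct reads excluded), equivalent to writing SAM and loading."""
        keep = ~self.is_construct
        cidx = np.zeros(int(keep.sum()), dtype=np.int32)
        start = self.read_start[keep]
        strand = self.strand[keep].astype(np.int8)
        rlen = np.full(start.size, self.read_length, dtype=np.int32)
        cidx, start, strand, rlen = alignment_io._dedup(cidx, start, strand, rlen)
        return Lane(
            sample_id=self.sample_id,
            lane_id=self.lane_id,
            library_id=self.library_id,
            chrom_names=[GENOME_CHROM],
            chrom_idx=cidx,
            start=start,
            strand=strand,
            read_length=rlen,
            total_raw_reads=self.n_reads,
            fragment_length=self.genome.config.fragment_length,
        )


def _fragment_weights(genome: SimulatedGenome, meth: MethylationTruth, k: float):
    """Per-start capture weights for genome and construct fragments."""
    L = genome.config.fragment_length
    G = len(genome.sequence)
    starts_g = np.arange(G - L + 1)
    m = meth.methylated_sites
    cnt = np.searchsorted(m, starts_g + L) - np.searchsorted(m, starts_g)
    w_g = 1.0 + k * cnt
    C = len(genome.construct_sequence)
    starts_c = np.arange(C - L + 1)
    mc = genome.construct_cpg_sites  # fully methylated
    cnt_c = np.searchsorted(mc, starts_c + L) - np.searchsorted(mc, starts_c)
    w_c = 1.0 + k * cnt_c
    return w_g, w_c


def simulate_lane(
    genome: SimulatedGenome,
    meth: MethylationTruth,
    mode: str = "captured",
    seed: int = 0,
    sample_id: str = "S1",
    lane_id: str = "L1",
    library_id: str = "lib1",
    config: SimConfig | None = None,
) -> SimulatedLane:
    """Draw one lane of reads by weighted fragment capture.

    ``captured`` uses weight 1 + k*mCpG; ``failed`` and ``input`` force
    k = 0 (uniform sampling).  The spike-in construct competes inside the
    same draw with total weight scaled by its copy number.  Reads are the
    5'-most ``read_length`` bases of the fragment on a random strand;
    duplicates are injected by resampling already-emitted reads.
    """
    cfg = config or genome.config
    if cfg.reads_per_lane < 1:
        raise ValueError("reads_per_lane must be >= 1")
    if mode not in ("captured", "failed", "input"):
        raise ValueError(f"unknown lane mode: {mode}")
    rng = np.random.default_rng(seed)
    k = cfg.capture_strength if mode == "captured" else 0.0
    w_g, w_c = _fragment_weights(genome, meth, k)
    w = np.concatenate([w_g, w_c * cfg.spikein_copies_per_genome])
    cdf = np.cumsum(w)

    n_total = cfg.reads_per_lane
    n_dup = int(rng.binomial(n_total, cfg.duplicate_rate))
    n_draw = n_total - n_dup
    picks = np.searchsorted(cdf, rng.random(n_draw) * cdf[-1], side="right")
    is_construct = picks >= w_g.size
    frag_start = np.where(is_construct, picks - w_g.size, picks)
    strand = (rng.random(n_draw) < 0.5).astype(np.int8)
    L, rl = cfg.fragment_length, cfg.read_length
    # + strand reads start at the fragment 5' end; - strand reads cover the
    # fragment's rightmost rl bases (their alignment start is end - rl)
    read_start = np.where(strand == 0, frag_start, frag_start + L - rl)

    if n_dup:
        src = rng.integers(0, n_draw, n_dup)
        is_construct = np.concatenate([is_construct, is_construct[src]])
        read_start = np.concatenate([read_start, read_start[src]])
        strand = np.concatenate([strand, strand[src]])
        frag_start = np.concatenate([frag_start, frag_start[src]])
    order = rng.permutation(read_start.size)
    is_construct, read_start, strand, frag_start = (
        is_construct[order],
        read_start[order],
        strand[order],
        frag_start[order],
    )

    gmask = ~is_construct
    key = read_start[gmask] * 2 + strand[gmask]
    truth = {
        "mode": mode,
        "seed": seed,
        "n_reads": int(n_total),
        "n_duplicates_injected": int(n_dup),
        "n_genome_reads": int(gmask.sum()),
        "construct_read_count": int(is_construct.sum()),
        "expected_unique_genome": int(np.unique(key).size),
        "fragment_starts": frag_start,
        "methylation_level": meth.level,
    }
    return SimulatedLane(
        sample_id=sample_id,
        lane_id=lane_id,
        library_id=library_id,
        mode=mode,
        genome=genome,
        is_construct=is_construct,
        read_start=read_start,
        strand=strand,
        read_length=rl,
        n_duplicates_injected=n_dup,
        truth=truth,
    )


def island_featureset(genome: SimulatedGenome, name: str = "islands") -> FeatureSet:
    df = pd.DataFrame(
        {
            "chrom": GENOME_CHROM,
            "start": [s for s, _ in genome.islands],
            "end": [e for _, e in genome.islands],
            "feature_id": [f"island_{i}" for i in range(len(genome.islands))],
        }
    )
    return FeatureSet(name=name, intervals=df)


@dataclass
class SampleSpec:
    sample_id: str
    group: str
    methylation_level: float
    lane_modes: tuple[str, ...] = ("captured",)
    library_id: str = ""


@dataclass
class CohortSim:
    genome: SimulatedGenome
    samples: list[SampleSpec]
    lanes: dict[str, list[SimulatedLane]]  # sample_id -> lanes
    methylation: dict[str, MethylationTruth]
    groups: dict[str, str]
    dmr_island_ids: list[str]
    manifest: list[ManifestEntry] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for ln in self.lanes[s.sample_id]:
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "lane_id": ln.lane_id,
                        "group": s.group,
                        "mode": ln.mode,
                        "methylation_level": s.methylation_level,
                        "n_duplicates": ln.n_duplicates_injected,
                        "construct_reads": ln.construct_read_count,
                    }
                )
        return pd.DataFrame(rows)


def simulate_cohort(
    config: SimConfig,
    samples: list[SampleSpec],
    dmr_fraction: float = 0.0,
    dmr_high: float = 0.9,
    dmr_low: float = 0.1,
    seed: int | None = None,
    out_dir: str | None = None,
) -> CohortSim:
    """Simulate a cohort on one shared genome with per-sample methylation.

    When ``dmr_fraction`` > 0 a seeded subset of islands is planted as truly
    differential: the first group label (sorted) methylates them with
    probability ``dmr_high`` and the second with ``dmr_low``; every other
    region follows the sample's own global level.  With ``out_dir`` the
    genome FASTA, one SAM per lane and a manifest.tsv are written.
    """
    if not samples:
        raise ValueError("cohort needs at least one sample")
    master = np.random.default_rng(config.seed if seed is None else seed)
    genome = simulate_genome(config)
    labels = sorted({s.group for s in samples})
    n_isl = len(genome.islands)
    n_dmr = int(round(dmr_fraction * n_isl))
    dmr_idx = master.choice(n_isl, size=n_dmr, replace=False) if n_dmr else np.empty(0, int)

    lanes: dict[str, list[SimulatedLane]] = {}
    meths: dict[str, MethylationTruth] = {}
    manifest: list[ManifestEntry] = []
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        genome.write_fasta(os.path.join(out_dir, "genome.fa"))

    for spec in samples:
        probs = np.full(n_isl, spec.methylation_level)
        if n_dmr:
            probs[dmr_idx] = dmr_high if spec.group == labels[0] else dmr_low
        meth = draw_methylation(
            genome,
            spec.methylation_level,
            np.random.default_rng(master.integers(2**31)),
            island_probs=probs,
        )
        meths[spec.sample_id] = meth
        lanes[spec.sample_id] = []
        lib = spec.library_id or f"lib_{spec.sample_id}"
        for j, mode in enumerate(spec.lane_modes):
            lane_id = f"{spec.sample_id}_L{j + 1}"
            ln = simulate_lane(
                genome,
                meth,
                mode=mode,
                seed=int(master.integers(2**31)),
                sample_id=spec.sample_id,
                lane_id=lane_id,
                library_id=lib,
                config=config,
            )
            lanes[spec.sample_id].append(ln)
            path = f"{lane_id}.sam"
            if out_dir:
                ln.to_sam(os.path.join(out_dir, path))
            manifest.append(
                ManifestEntry(
                    sample_id=spec.sample_id,
                    lane_id=lane_id,
                    library_id=lib,
                    path=path,
                    fragment_length=config.fragment_length,
                    total_raw_reads=ln.n_reads,
                    group=spec.group,
                )
            )

    if out_dir:
        pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "lane_id": m.lane_id,
                    "library_id": m.library_id,
                    "path": m.path,
                    "fragment_length": m.fragment_length,
                    "total_raw_reads": m.total_raw_reads,
                    "group": m.group,
                }
                for m in manifest
            ]
        ).to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
        island_featureset(genome).intervals.to_csv(
            os.path.join(out_dir, "islands.bed"),
            sep="\t",
            index=False,
            header=False,
        )

    return CohortSim(
        genome=genome,
        samples=samples,
        lanes=lanes,
        methylation=meths,
        groups={s.sample_id: s.group for s in samples},
        dmr_island_ids=[f"island_{i}" for i in sorted(dmr_idx.tolist())],
        manifest=manifest,
    )
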