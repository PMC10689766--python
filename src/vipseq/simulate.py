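"""Synthetic lysogen genomes and virion read pools with known truth.

The generator builds a random bacterial chromosome with prophages inserted
at chosen positions, then draws error-free 150 bp paired-end reads the way
a virion-DNA library produces them:

* each induced prophage contributes reads in proportion to its DNA mass
  (titre x genome length) — the read pool is multinomial across prophages
  plus a small chromosomal background of residual undigested host DNA;
* prophage fragments are drawn uniformly on the *circular* excised genome,
  so a predictable fraction of pairs straddles the att junction; on the
  linear reference those appear as outward-facing discordant pairs, and
  reads crossing the junction themselves appear clipped exactly at attL or
  attR;
* optionally, extra host reads form a step-wise decaying coverage gradient
  on one flank of a prophage, emulating lateral transduction by successive
  capsid headfuls.

Reads are emitted pre-aligned in a truth SAM (with correct positions,
orientations and clip structure) so detection is testable without running
an aligner; FASTQ can also be written for end-to-end runs through a real
mapper.  The truth DNA mass is derived from the configured titres through
the same mass relation the quantification module inverts, so titre
estimates on simulated data are unbiased by construction.  All randomness
flows from the single seed; identical configs give identical output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io import AlignmentRecord, GenomeRecord, Interval
from .quantify import AVOGADRO, MOLAR_MASS_PER_BP, NG_PER_G

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


@dataclass(frozen=True)
class ProphageSpec:
    length_bp: int
    gc: float
    titre: float  # virions per mL of overnight culture
    insertion_pos: int  # position in the prophage-free host backbone


@dataclass(frozen=True)
class LateralTransductionSpec:
    prophage_index: int = 0
    side: str = "right"  # flank carrying the gradient
    extent_bp: int = 200_000
    headful_bp: int = 40_000
    edge_enrichment: float = 20.0  # depth multiple over background at the edge


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_len_bp: int = 1_000_000  # prophage-free backbone length
    genome_gc: float = 0.5
    prophages: tuple[ProphageSpec, ...] = (
        ProphageSpec(length_bp=20_000, gc=0.45, titre=1e7, insertion_pos=300_000),
        ProphageSpec(length_bp=40_000, gc=0.55, titre=5e6, insertion_pos=700_000),
    )
    background_read_fraction: float = 0.02  # residual undigested host DNA
    read_len_bp: int = 150
    insert_mean_bp: int = 500
    insert_sd_bp: float = 50.0
    total_read_pairs: int = 200_000
    supernatant_volume_ml: float = 30.0
    lateral_transduction: LateralTransductionSpec | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.background_read_fraction < 1:
            raise ValueError("background_read_fraction must be in [0, 1)")
        if not 0 < self.genome_gc < 1:
            raise ValueError("genome_gc must be in (0, 1)")
        for p in self.prophages:
            if not 0 <= p.insertion_pos <= self.genome_len_bp:
                raise ValueError("insertion_pos outside host backbone")
            if p.length_bp < self.insert_mean_bp:
                raise ValueError(
                    f"prophage of {p.length_bp} bp shorter than the mean insert"
                )
        positions = [p.insertion_pos for p in self.prophages]
        if len(set(positions)) != len(positions):
            raise ValueError("overlapping prophage insertions")


@dataclass
class SimRead:
    """One simulated read with its true origin and alignment."""

    read_id: str
    mate: int  # 1 or 2
    category: str  # "prophage_<k>", "background", "lateral"
    spans_junction: bool  # the read pair's fragment crosses attL/attR
    alignment: AlignmentRecord
    frag_start: int  # circular (prophage) or linear (host) fragment start
    frag_len: int


@dataclass
class TruthSet:
    genome: GenomeRecord
    prophages: list[Interval]
    titres: dict[str, float]  # label -> virions/mL
    expected_fractions: dict[str, float]  # label -> expected read fraction
    m_dna_ng_per_ml: float
    reads: list[SimRead] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def alignments(self) -> list[AlignmentRecord]:
        return [r.alignment for r in self.reads]


# ---------------------------------------------------------------------------
# genome construction


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    at = (1.0 - gc) / 2.0
    probs = np.array([at, gc / 2.0, gc / 2.0, at])
    return rng.choice(_BASES, size=n, p=probs).tobytes().decode("ascii")


def make_lysogen(cfg: SimulationConfig, genome_id: str = "sim_chrom") -> TruthSet:
    """Host backbone with prophages inserted; truth in final coordinates."""
    rng = np.random.default_rng([cfg.seed, 0])
    host = random_sequence(cfg.genome_len_bp, cfg.genome_gc, rng)
    ordered = sorted(cfg.prophages, key=lambda p: p.insertion_pos)
    pieces: list[str] = []
    intervals: list[Interval] = []
    titres: dict[str, float] = {}
    cursor = 0
    offset = 0
    for k, p in enumerate(ordered):
        pieces.append(host[cursor:p.insertion_pos])
        seq = random_sequence(p.length_bp, p.gc, rng)
        label = f"prophage_{k + 1}"
        start = p.insertion_pos + offset
        intervals.append(Interval(genome_id, start, start + p.length_bp, label=label))
        titres[label] = p.titre
        pieces.append(seq)
        cursor = p.insertion_pos
        offset += p.length_bp
    pieces.append(host[cursor:])
    genome = GenomeRecord(id=genome_id, sequence="".join(pieces))

    # expected read fractions = DNA mass shares; background takes the rest
    masses = {iv.label: titres[iv.label] * iv.length for iv in intervals}
    total_mass = sum(masses.values())
    bg = cfg.background_read_fraction
    fractions = {
        lab: (1.0 - bg) * (m / total_mass) if total_mass > 0 else 0.0
        for lab, m in masses.items()
    }
    # grams/mL of prophage DNA from the titres; the background share of the
    # library dilutes it, so total eluted mass scales by 1/(1 - bg)
    prophage_mass_g = sum(
        titres[iv.label] * iv.length * MOLAR_MASS_PER_BP / AVOGADRO for iv in intervals
    )
    m_dna = prophage_mass_g * NG_PER_G / (1.0 - bg) if total_mass > 0 else 0.0
    return TruthSet(
        genome=genome,
        prophages=intervals,
        titres=titres,
        expected_fractions=fractions,
        m_dna_ng_per_ml=m_dna,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# read simulation


def _circular_read_alignment(
    circ_start: int, read_len: int, L: int, p0: int, strand: str, genome_id: str,
    read_id: str,
) -> AlignmentRecord:
    """Alignment of a read at circular offset ``circ_start`` on a prophage
    occupying [p0, p0+L) of the linear reference.

    A read crossing the circular junction maps as the longer piece, with
    the shorter piece soft-clipped: the clip boundary of a right-edge piece
    sits exactly on attR (= p0 + L), of a left-edge piece exactly on attL
    (= p0)."""
    c0 = circ_start % L
    if c0 + read_len <= L:
        return AlignmentRecord(
            read_id=read_id, genome_id=genome_id, pos=p0 + c0, strand=strand,
            mapq=60, aligned_len=read_len,
        )
    right_len = L - c0
    left_len = read_len - right_len
    if right_len >= left_len:
        return AlignmentRecord(
            read_id=read_id, genome_id=genome_id, pos=p0 + c0, strand=strand,
            mapq=60, aligned_len=right_len, clip_right=left_len,
        )
    return AlignmentRecord(
        read_id=read_id, genome_id=genome_id, pos=p0, strand=strand,
        mapq=60, aligned_len=left_len, clip_left=right_len,
    )


def _pair_with_mates(a: AlignmentRecord, b: AlignmentRecord,
                     proper: bool) -> tuple[AlignmentRecord, AlignmentRecord]:
    a = replace(a, mate_pos=b.pos, mate_strand=b.strand, is_proper_pair=proper)
    b = replace(b, mate_pos=a.pos, mate_strand=a.strand, is_proper_pair=proper)
    return a, b


def _draw_fragment_lengths(
    n: int, cfg: SimulationConfig, rng: np.random.Generator, upper: int
) -> np.ndarray:
    flens = rng.normal(cfg.insert_mean_bp, cfg.insert_sd_bp, size=n)
    return np.clip(np.rint(flens).astype(int), cfg.read_len_bp, upper)


def simulate_virion_reads(truth: TruthSet, cfg: SimulationConfig | None = None) -> TruthSet:
    """Draw the multinomial read pool and attach truth alignments.

    Returns ``truth`` with its ``reads`` list populated.  Categories are
    drawn multinomially: each prophage with probability proportional to its
    DNA mass (titre x length) scaled by (1 - background fraction), the host
    background with the remaining probability.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    rl = cfg.read_len_bp
    genome = truth.genome
    labels = [iv.label for iv in truth.prophages]
    probs = [truth.expected_fractions[lab] for lab in labels]
    probs.append(max(0.0, 1.0 - sum(probs)))
    counts = rng.multinomial(cfg.total_read_pairs, np.array(probs) / sum(probs))

    reads: list[SimRead] = []
    pair_no = 0
    for iv, n_pairs in zip(truth.prophages, counts[: len(labels)]):
        L = iv.length
        starts = rng.integers(0, L, size=n_pairs)
        flens = _draw_fragment_lengths(n_pairs, cfg, rng, upper=L)
        for s, flen in zip(starts.tolist(), flens.tolist()):
            pair_no += 1
            rid = f"sim_{pair_no:07d}"
            spans = s + flen > L
            a = _circular_read_alignment(s, rl, L, iv.start, "+", genome.id, rid)
            b = _circular_read_alignment(s + flen - rl, rl, L, iv.start, "-", genome.id, rid)
            a, b = _pair_with_mates(a, b, proper=not spans)
            reads.append(SimRead(rid, 1, iv.label, spans, a, s, flen))
            reads.append(SimRead(rid, 2, iv.label, spans, b, s, flen))
    # background: uniform fragments over the (linear) lysogen chromosome
    n_bg = int(counts[-1])
    flens = _draw_fragment_lengths(n_bg, cfg, rng, upper=genome.length)
    starts = rng.integers(0, np.maximum(genome.length - flens + 1, 1))
    for s, flen in zip(starts.tolist(), flens.tolist()):
        pair_no += 1
        rid = f"sim_{pair_no:07d}"
        a = AlignmentRecord(read_id=rid, genome_id=genome.id, pos=s, strand="+",
                            mapq=60, aligned_len=rl)
        b = AlignmentRecord(read_id=rid, genome_id=genome.id, pos=s + flen - rl,
                            strand="-", mapq=60, aligned_len=rl)
        a, b = _pair_with_mates(a, b, proper=True)
        reads.append(SimRead(rid, 1, "background", False, a, s, flen))
        reads.append(SimRead(rid, 2, "background", False, b, s, flen))
    truth.reads = reads
    return truth


def apply_lateral_transduction(truth: TruthSet, cfg: SimulationConfig | None = None) -> TruthSet:
    """Append host reads forming a headful-packaging coverage gradient.

    The flank of ``extent_bp`` next to the chosen prophage is divided into
    ``extent_bp / headful_bp`` steps; step k (k = 0 at the prophage edge)
    receives extra depth (edge_enrichment - 1) x background x (n - k)/n, so
    the profile steps down from ~edge_enrichment x background at the edge
    to background beyond the extent.  Extra pairs are Poisson per step.
    The truth DNA mass is rescaled to include the transduced DNA so read
    fractions stay mass shares.
    """
    cfg = cfg or truth.config
    lat = cfg.lateral_transduction
    if lat is None:
        raise ValueError("lateral_transduction is not configured")
    if not truth.reads:
        raise ValueError("simulate_virion_reads must run first")
    rng = np.random.default_rng([cfg.seed, 2])
    rl = cfg.read_len_bp
    genome = truth.genome
    iv = truth.prophages[lat.prophage_index]
    n_before = len(truth.reads) // 2

    # background depth implied by the configured pool
    bg_pairs = cfg.total_read_pairs * cfg.background_read_fraction
    bg_depth = bg_pairs * 2 * rl / genome.length
    n_steps = max(1, int(np.ceil(lat.extent_bp / lat.headful_bp)))

    pair_no = n_before
    for k in range(n_steps):
        if lat.side == "right":
            lo = iv.end + k * lat.headful_bp
            hi = min(genome.length, lo + lat.headful_bp, iv.end + lat.extent_bp)
        else:
            hi = iv.start - k * lat.headful_bp
            lo = max(0, hi - lat.headful_bp, iv.start - lat.extent_bp)
        if hi <= lo:
            break
        extra_depth = (lat.edge_enrichment - 1.0) * bg_depth * (n_steps - k) / n_steps
        lam = extra_depth * (hi - lo) / (2 * rl)
        n_extra = int(rng.poisson(lam))
        if n_extra == 0:
            continue
        flens = _draw_fragment_lengths(n_extra, cfg, rng, upper=max(hi - lo, rl))
        starts = lo + rng.integers(0, np.maximum(hi - lo - flens + 1, 1))
        for s, flen in zip(starts.tolist(), flens.tolist()):
            pair_no += 1
            rid = f"lat_{pair_no:07d}"
            a = AlignmentRecord(read_id=rid, genome_id=genome.id, pos=int(s),
                                strand="+", mapq=60, aligned_len=rl)
            b = AlignmentRecord(read_id=rid, genome_id=genome.id,
                                pos=int(s) + flen - rl, strand="-", mapq=60,
                                aligned_len=rl)
            a, b = _pair_with_mates(a, b, proper=True)
            truth.reads.append(SimRead(rid, 1, "lateral", False, a, int(s), flen))
            truth.reads.append(SimRead(rid, 2, "lateral", False, b, int(s), flen))
    n_after = len(truth.reads) // 2
    if n_before:
        truth.m_dna_ng_per_ml *= n_after / n_before
    return truth


def simulate(cfg: SimulationConfig) -> TruthSet:
    """Full generator: genome, read pool, optional transduction gradient."""
    truth = make_lysogen(cfg)
    truth = simulate_virion_reads(truth, cfg)
    if cfg.lateral_transduction is not None:
        truth = apply_lateral_transduction(truth, cfg)
    return truth


# ---------------------------------------------------------------------------
# serialisation


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _read_sequence(read: SimRead, truth: TruthSet, cfg: SimulationConfig) -> str:
    """Reconstruct the read's base sequence from its true origin."""
    rl = cfg.read_len_bp
    genome = truth.genome.sequence
    if read.category == "background" or read.category == "lateral":
        frag = genome[read.frag_start:read.frag_start + read.frag_len]
    else:
        iv = next(p for p in truth.prophages if p.label == read.category)
        circ = genome[iv.start:iv.end]
        s = read.frag_start
        e = s + read.frag_len
        frag = circ[s:] + circ[: e % iv.length] if e > iv.length else circ[s:e]
    return frag[:rl] if read.mate == 1 else _revcomp(frag[-rl:])


def write_truth_sam(truth: TruthSet, path: str | Path) -> None:
    """Write the simulated alignments as a coordinate-unsorted SAM file."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": truth.genome.id, "LN": truth.genome.length}],
    })
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read in truth.reads:
            aln = read.alignment
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.reference_id = 0
            seg.reference_start = aln.pos
            seg.mapping_quality = aln.mapq
            cig = []
            if aln.clip_left:
                cig.append((4, aln.clip_left))
            cig.append((0, aln.aligned_len))
            if aln.clip_right:
                cig.append((4, aln.clip_right))
            seg.cigartuples = cig
            flag = 0x1  # paired
            flag |= 0x40 if read.mate == 1 else 0x80
            if aln.strand == "-":
                flag |= 0x10
            if aln.mate_strand == "-":
                flag |= 0x20
            if aln.is_proper_pair:
                flag |= 0x2
            seg.flag = flag
            seg.next_reference_id = 0
            seg.next_reference_start = aln.mate_pos if aln.mate_pos is not None else -1
            out.write(seg)


def write_fastq(truth: TruthSet, prefix: str | Path, compress: bool = True) -> tuple[Path, Path]:
    """Paired FASTQ files (R1/R2) reconstructed from read origins."""
    cfg = truth.config
    suffix = ".fastq.gz" if compress else ".fastq"
    paths = (Path(f"{prefix}_R1{suffix}"), Path(f"{prefix}_R2{suffix}"))
    opener = gzip.open if compress else open
    quals = "I" * cfg.read_len_bp
    handles = [opener(p, "wt") for p in paths]
    try:
        for read in truth.reads:
            seq = _read_sequence(read, truth, cfg)
            fh = handles[read.mate - 1]
            fh.write(f"@{read.read_id}/{read.mate}\n{seq}\n+\n{quals}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths
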