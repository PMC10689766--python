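"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions used throughout the package:

* every coordinate stored internally is 0-based, half-open;
* every BED emitted is 0-based, half-open;
* human-readable reports are 1-based inclusive and labelled as such.

FASTA is handled through Biopython, SAM/BAM through pysam; this module only
adds the thin domain types (:class:`GenomeRecord`, :class:`Interval`,
:class:`AlignmentRecord`) the rest of the pipeline shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class ReferenceMismatchError(ValueError):
    """Raised when alignments reference a genome that was not provided."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence (lysogen chromosome or phage genome)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_fraction(self) -> float:
        """GC fraction over unambiguous {A,C,G,T} bases only."""
        acgt = sum(self.sequence.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        gc = self.sequence.count("G") + self.sequence.count("C")
        return gc / acgt


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    genome_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.label!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def intersection_len(self, other: "Interval") -> int:
        if self.genome_id != other.genome_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment (subset of SAM semantics, 0-based positions)."""

    read_id: str
    genome_id: str
    pos: int
    strand: str  # "+" or "-"
    mapq: int
    aligned_len: int  # reference bases consumed
    clip_left: int = 0
    clip_right: int = 0
    mate_pos: int | None = None
    mate_strand: str | None = None
    is_primary: bool = True
    is_proper_pair: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0 or self.aligned_len < 1:
            raise ValueError("pos must be >= 0 and aligned_len >= 1")
        if self.clip_left < 0 or self.clip_right < 0:
            raise ValueError("clip lengths must be >= 0")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        """Exclusive end of the aligned reference span."""
        return self.pos + self.aligned_len


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T.  An empty file or
    duplicate ids raise :class:`FormatError`.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# SAM / BAM


def _record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cig = seg.cigartuples or []
    # soft (4) and hard (5) clips at either end of the CIGAR
    clip_left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    clip_right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    mate_pos = seg.next_reference_start if seg.is_paired and seg.next_reference_start >= 0 else None
    mate_strand = None
    if seg.is_paired and mate_pos is not None:
        mate_strand = "-" if seg.mate_is_reverse else "+"
    return AlignmentRecord(
        read_id=seg.query_name,
        genome_id=seg.reference_name,
        pos=seg.reference_start,
        strand="-" if seg.is_reverse else "+",
        mapq=seg.mapping_quality,
        aligned_len=seg.reference_length or 1,
        clip_left=clip_left,
        clip_right=clip_right,
        mate_pos=mate_pos,
        mate_strand=mate_strand,
        is_primary=not (seg.is_secondary or seg.is_supplementary),
        is_proper_pair=seg.is_proper_pair,
    )


def read_alignments(
    path: str | Path,
    mapq_min: int = 1,
    genomes: Sequence[GenomeRecord] | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream primary alignments with ``mapq >= mapq_min`` from SAM/BAM.

    Unmapped, secondary and supplementary records are skipped; mapq below the
    gate drops multi-mapping ("non-specific") reads, whose conventional
    encoding is mapq 0.  SAM's 1-based positions arrive 0-based via pysam.

    If ``genomes`` is given, every header reference must be among their ids,
    otherwise :class:`ReferenceMismatchError` is raised.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if genomes is not None:
            known = {g.id for g in genomes}
            missing = set(fh.references) - known
            if missing:
                raise ReferenceMismatchError(
                    f"alignment references not in provided genomes: {sorted(missing)}"
                )
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.mapping_quality < mapq_min:
                continue
            yield _record_from_pysam(seg)


# ---------------------------------------------------------------------------
# Intervals (BED / 1-based TSV)

_DIALECTS = ("bed", "tsv1")


def read_intervals(path: str | Path, dialect: str = "bed") -> list[Interval]:
    """Read intervals, normalising to 0-based half-open.

    ``dialect`` must be declared explicitly: ``"bed"`` (0-based half-open,
    columns chrom/start/end[/name]) or ``"tsv1"`` (tab-separated with a
    header line ``genome_id  start  end  label`` using 1-based inclusive
    coordinates, the convention of spreadsheet exports).
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown interval dialect {dialect!r}; use one of {_DIALECTS}")
    intervals: list[Interval] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if dialect == "tsv1" and lines:
        lines = lines[1:]  # header row
    for i, ln in enumerate(lines):
        parts = ln.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i + 1}: expected >= 3 tab-separated columns")
        gid, s, e = parts[0], parts[1], parts[2]
        label = parts[3] if len(parts) > 3 else f"iv{i + 1}"
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 1}: non-integer coordinates") from exc
        if dialect == "tsv1":
            start -= 1  # 1-based inclusive -> 0-based half-open
        if start >= end:
            raise FormatError(
                f"{path}: line {i + 1}: empty/inverted interval after normalization"
            )
        intervals.append(Interval(genome_id=gid, start=start, end=end, label=label))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.genome_id}\t{iv.start}\t{iv.end}\t{iv.label}\n")
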