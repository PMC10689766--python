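"""Absolute virion titres from eluted DNA mass and mapped-read fractions.

The virion preparation is DNase-treated, so essentially all eluted DNA is
encapsidated phage DNA.  The measured mass, expressed per 1 mL of overnight
culture, is partitioned among the active prophages by their read fractions
and converted to genome copies per mL:

    titre = m_DNA * N_A / (M_nt * L_prophage) * (r_pp / r_tot)

where m_DNA is the eluted DNA mass per mL (grams), N_A Avogadro's constant,
M_nt the average molar mass of a DNA nucleotide pair per bp of duplex
(617.96 g/mol/bp), L_prophage the prophage genome length in bp, and
r_pp / r_tot the fraction of mapped reads falling in the prophage region.

The same arithmetic run backwards gives the method's detection limit: the
smallest measurable DNA mass, expressed as virions of an average-sized
phage in the original supernatant, corrected for losses in the
concentration step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .detection import ProphageCall
from .io import AlignmentRecord, Interval

#: Avogadro's constant, 1/mol.
AVOGADRO = 6.02214076e23
#: Average molar mass of double-stranded DNA per base pair, g/mol/bp.
MOLAR_MASS_PER_BP = 617.96

NG_PER_G = 1e9


@dataclass(frozen=True)
class QuantInput:
    """Inputs to the titre formula for one prophage."""

    m_dna_ng_per_ml: float  # eluted DNA mass per 1 mL overnight culture
    r_pp: int  # reads mapped to the prophage region
    r_tot: int  # total mapped reads
    length_bp: int  # L_prophage

    def __post_init__(self) -> None:
        if not 0 <= self.r_pp <= self.r_tot:
            raise ValueError("need 0 <= r_pp <= r_tot")
        if self.length_bp <= 0:
            raise ValueError("prophage length must be positive")
        if self.m_dna_ng_per_ml < 0:
            raise ValueError("DNA mass must be non-negative")


@dataclass(frozen=True)
class TitreEstimate:
    label: str
    titre: float  # virions (genome copies) per mL
    inputs: QuantInput


@dataclass(frozen=True)
class LimitConfig:
    """Wet-lab parameters determining the quantification detection limit."""

    qubit_limit_ng: float = 0.1  # minimum detectable mass in the assayed aliquot
    elution_volume_ul: float = 24.0
    assay_volume_ul: float = 5.0
    supernatant_volume_ml: float = 30.0
    mean_prophage_len_bp: int = 41_000
    concentration_loss_fraction: float = 0.47  # virions lost during concentration

    def __post_init__(self) -> None:
        if not 0 <= self.concentration_loss_fraction < 1:
            raise ValueError("concentration_loss_fraction must be in [0, 1)")
        if self.assay_volume_ul > self.elution_volume_ul:
            raise ValueError("assay volume cannot exceed elution volume")
        if min(self.elution_volume_ul, self.assay_volume_ul,
               self.supernatant_volume_ml) <= 0:
            raise ValueError("volumes must be positive")


# ---------------------------------------------------------------------------


def titre(q: QuantInput) -> float:
    """Absolute titre in virions/mL from the mass-partition formula."""
    if q.r_tot == 0:
        raise ValueError("r_tot is zero: titre undefined without mapped reads")
    m_g = q.m_dna_ng_per_ml / NG_PER_G
    return (m_g * AVOGADRO) / (MOLAR_MASS_PER_BP * q.length_bp) * (q.r_pp / q.r_tot)


def count_prophage_reads(
    alignments: Iterable[AlignmentRecord],
    calls: Sequence[ProphageCall | Interval],
) -> tuple[dict[str, int], int]:
    """Assign retained reads to prophage calls by leftmost mapped position.

    Returns ``({call label: r_pp}, r_tot)``.  Calls must be disjoint;
    leftmost-position binning keeps the per-call counts exactly multinomial
    in the fragment origins.
    """
    intervals = [c.interval if isinstance(c, ProphageCall) else c for c in calls]
    ordered = sorted(intervals, key=lambda iv: (iv.genome_id, iv.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.genome_id == b.genome_id and b.start < a.end:
            raise ValueError(f"overlapping calls {a.label!r} and {b.label!r}")
    counts = {iv.label: 0 for iv in intervals}
    r_tot = 0
    for aln in alignments:
        r_tot += 1
        for iv in intervals:
            if iv.genome_id == aln.genome_id and iv.contains(aln.pos):
                counts[iv.label] += 1
                break
    return counts, r_tot


def quantify_calls(
    alignments: Iterable[AlignmentRecord],
    calls: Sequence[ProphageCall],
    m_dna_ng_per_ml: float,
) -> list[TitreEstimate]:
    """Per-prophage titres for a sample: count reads, apply the formula."""
    counts, r_tot = count_prophage_reads(alignments, calls)
    estimates = []
    for call in calls:
        q = QuantInput(
            m_dna_ng_per_ml=m_dna_ng_per_ml,
            r_pp=counts[call.label],
            r_tot=r_tot,
            length_bp=call.length_bp,
        )
        estimates.append(TitreEstimate(label=call.label, titre=titre(q), inputs=q))
    return estimates


def detection_limit(cfg: LimitConfig) -> float:
    """Smallest quantifiable titre, in virions/mL of original supernatant.

    The Qubit aliquot is a measurement, not a consumption, so the minimum
    detectable *total* eluted mass is the per-aliquot limit scaled by
    elution/assay volume; spread over the supernatant volume and converted
    through the titre formula at r_pp/r_tot = 1 for an average-length
    prophage, then inflated for virions lost in the concentration step.
    """
    min_total_mass_ng = cfg.qubit_limit_ng * cfg.elution_volume_ul / cfg.assay_volume_ul
    m_per_ml = min_total_mass_ng / cfg.supernatant_volume_ml
    q = QuantInput(m_dna_ng_per_ml=m_per_ml, r_pp=1, r_tot=1,
                   length_bp=cfg.mean_prophage_len_bp)
    return titre(q) / (1.0 - cfg.concentration_loss_fraction)


def induction_rate(titre_per_ml: float, cfu_per_ml: float, burst_size: float) -> float:
    """Fraction of cells lysing per culture: titre / (CFU * burst size)."""
    if cfu_per_ml <= 0 or burst_size <= 0:
        raise ValueError("CFU/mL and burst size must be positive")
    return titre_per_ml / (cfu_per_ml * burst_size)


def aggregate_strain(
    titres: Sequence[TitreEstimate | float], cfu_per_ml: float | None = None
) -> tuple[float, float | None]:
    """Strain-level aggregate titre and virion/CFU ratio.

    The ratio is ``None`` (reported as missing) when no CFU count is
    available.
    """
    total = sum(t.titre if isinstance(t, TitreEstimate) else float(t) for t in titres)
    ratio = total / cfu_per_ml if cfu_per_ml else None
    return total, ratio


def mass_shares_ng(estimates: Sequence[TitreEstimate]) -> dict[str, float]:
    """Per-prophage DNA mass share implied by each titre, in ng/mL.

    Inverts the titre formula; summing these plus the residual (non-
    prophage) share reproduces m_DNA exactly — a conservation check used in
    the test suite.
    """
    return {
        e.label: e.titre * e.inputs.length_bp * MOLAR_MASS_PER_BP / AVOGADRO * NG_PER_G
        for e in estimates
    }
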