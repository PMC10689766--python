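"""Active-prophage detection from virion-read coverage and junction reads.

A spontaneously induced prophage excises from the chromosome, circularises
(joining attL and attR) and packages its DNA into virions.  Sequencing the
virion DNA and mapping it back to the lysogen assembly therefore produces

* an island of high read coverage over the integrated prophage, against a
  near-zero chromosomal background, and
* junction-spanning evidence at the att sites: read pairs whose fragment
  crossed the circular junction map as outward-facing discordant pairs on
  the linear reference, while reads that themselves cross the junction map
  clipped, the clip boundary sitting exactly on attL or attR.

Detection proceeds in two stages: coarse candidate islands from coverage
(`segment_islands`), then exact boundary refinement from junction evidence
(`refine_boundaries`).  A decaying coverage gradient on one flank of a call
— the signature of lateral transduction by headful packaging — is summarised
by `flanking_enrichment`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import AlignmentRecord, GenomeRecord, Interval

logger = logging.getLogger(__name__)

# Defaults: the smallest induced prophages observed are ~16 kbp, and virion
# libraries carry very little chromosomal background, so a coarse 5x-over-
# background, >=5 kb island rule is permissive while excluding noise.
MIN_FOLD = 5.0
MIN_LEN_BP = 5_000
MERGE_GAP_BP = 2_000
SEARCH_WINDOW_BP = 2_000
MAX_INSERT_BP = 1_500
MIN_SUPPORT = 2
MIN_CLIP_BP = 20
MAX_BACKGROUND_ROUNDS = 5


@dataclass
class CoverageProfile:
    """Per-base alignment depth plus a robust chromosomal background estimate."""

    genome_id: str
    depth: np.ndarray  # int array, length == genome length
    background: float = 0.0

    @property
    def length(self) -> int:
        return int(self.depth.shape[0])

    def mean_depth(self, start: int, end: int) -> float:
        return float(self.depth[start:end].mean()) if end > start else 0.0


@dataclass(frozen=True)
class PairSupport:
    """An outward-facing read pair bridging both edges of a candidate."""

    left_anchor_pos: int  # leftmost mapped base of the attL-side mate
    right_anchor_pos: int  # leftmost mapped base of the attR-side mate
    orientation_ok: bool
    left_anchor_end: int = 0  # exclusive end of the attL-side mate
    right_anchor_end: int = 0  # exclusive end of the attR-side mate


@dataclass(frozen=True)
class SplitSupport:
    """A clipped alignment whose clip boundary marks an att site."""

    side: str  # "left" (clip at attL) or "right" (clip at attR)
    clip_pos: int
    partner_pos: int | None = None  # mate position at the other edge, if seen


@dataclass
class JunctionEvidence:
    candidate: Interval
    pair_support: list[PairSupport] = field(default_factory=list)
    split_support: list[SplitSupport] = field(default_factory=list)

    @property
    def support_count(self) -> int:
        """Orientation-consistent pairs plus split reads."""
        return sum(p.orientation_ok for p in self.pair_support) + len(self.split_support)


@dataclass
class ProphageCall:
    """An active prophage: interval, junction support and summary stats."""

    interval: Interval
    support_count: int
    mean_depth: float = 0.0
    confidence: str = "coverage_only"  # or "junction"
    gc_relative: float = 0.0

    @property
    def length_bp(self) -> int:
        return self.interval.length

    @property
    def label(self) -> str:
        return self.interval.label


@dataclass
class FlankReport:
    call: ProphageCall
    side: str  # "left" or "right"
    window_bp: int
    flank_mean_depth: float
    enrichment: float
    decay_slope: float  # log-depth units per bp over the window
    truncated: bool = False


# ---------------------------------------------------------------------------
# Coverage


def compute_coverage(
    alignments: Iterable[AlignmentRecord], genome: GenomeRecord
) -> CoverageProfile:
    """Per-base depth of retained alignments (alignments, not fragments).

    Overlapping mates are double-counted; the simulation oracles apply the
    same convention.  The background field is filled by `segment_islands`.
    """
    n = genome.length
    diff = np.zeros(n + 1, dtype=np.int64)
    seen = 0
    for aln in alignments:
        if aln.genome_id != genome.id:
            continue
        start = min(aln.pos, n)
        end = min(aln.end, n)
        if end > start:
            diff[start] += 1
            diff[end] -= 1
            seen += 1
    if seen == 0:
        logger.warning("no retained alignments on %s; empty coverage profile", genome.id)
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(genome_id=genome.id, depth=depth, background=0.0)


def _runs_at_least(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


_BACKGROUND_WINDOW_BP = 1_000


def _robust_background(depth: np.ndarray, outside: np.ndarray | None = None,
                       window: int = _BACKGROUND_WINDOW_BP) -> float:
    """Median of window-mean depths over non-island positions.

    Virion-library backgrounds are sparse (per-base depth well below 1), so
    a per-base median collapses to zero; averaging in fixed windows first
    recovers the background rate while the median across windows keeps
    prophage islands from inflating it.  Windows with less than half their
    bases outside the islands are ignored."""
    if depth.size == 0:
        return 0.0
    if outside is None:
        outside = np.ones(depth.shape[0], dtype=bool)
    n_win = depth.shape[0] // window
    if n_win == 0:
        d = depth[outside]
        return float(d.mean()) if d.size else 0.0
    d = depth[: n_win * window].reshape(n_win, window)
    m = outside[: n_win * window].reshape(n_win, window)
    n_out = m.sum(axis=1)
    keep = n_out >= window // 2
    if not keep.any():
        return 0.0
    means = (d * m).sum(axis=1)[keep] / n_out[keep]
    return float(np.median(means))


def segment_islands(
    profile: CoverageProfile,
    min_fold: float = MIN_FOLD,
    min_len_bp: int = MIN_LEN_BP,
    merge_gap_bp: int = MERGE_GAP_BP,
    max_rounds: int = MAX_BACKGROUND_ROUNDS,
) -> list[Interval]:
    """Candidate prophage islands: runs of depth >= min_fold x background.

    Thresholding happens on 1 kb window-mean depth, not per-base depth: the
    chromosomal background of a virion library sits well below 1x, where
    per-base Poisson noise crosses any small multiple of the background,
    while window means separate cleanly.  Junction refinement restores
    base-exact boundaries afterwards, so window-granular island edges cost
    nothing.

    The initial background is the median of window-mean depths over the
    whole genome (robust while islands cover a minority of it).  Once an
    island set exists the background is the plain mean depth outside the
    islands, and the segmentation is repeated until the island set is
    stable (hard cap ``max_rounds``; non-convergence keeps the last set and
    warns).  The outside mean, not the outside median, is used for
    re-estimation: at the sub-1x backgrounds of virion libraries the
    window-mean distribution is discrete and skewed, and its median jumps
    between levels as windows are excluded, which can feed back into a
    collapsing threshold; the mean is stable and, with the islands already
    excluded, no longer needs to resist contamination.  With a zero background but nonzero depth (a strictly
    virion-only library) every covered run becomes a candidate, flagged by
    a warning.
    """
    depth = profile.depth
    islands: list[tuple[int, int]] = []
    background = _robust_background(depth) if depth.size else 0.0
    window = _BACKGROUND_WINDOW_BP
    n = depth.shape[0]
    if n:
        edges = np.arange(0, n, window)
        win_sums = np.add.reduceat(depth, edges)
        win_lens = np.diff(np.append(edges, n))
        win_means = win_sums / win_lens
    for _round in range(max_rounds):
        if background > 0:
            win_mask = win_means >= min_fold * background
            runs = [
                (int(edges[s]), int(min(edges[e - 1] + win_lens[e - 1], n)))
                for s, e in _runs_at_least(win_mask)
            ]
        else:
            if depth.any():
                logger.warning(
                    "%s: zero background with nonzero depth; treating every "
                    "covered run as a candidate",
                    profile.genome_id,
                )
            runs = _runs_at_least(depth > 0)
        runs = _merge_runs(runs, merge_gap_bp)
        new_islands = [(s, e) for s, e in runs if e - s >= min_len_bp]
        outside = np.ones(depth.shape[0], dtype=bool)
        for s, e in new_islands:
            outside[s:e] = False
        new_background = float(depth[outside].mean()) if outside.any() else 0.0
        converged = new_islands == islands and np.isclose(new_background, background)
        islands, background = new_islands, new_background
        if converged:
            break
    else:
        logger.warning("%s: island segmentation did not converge in %d rounds",
                       profile.genome_id, max_rounds)
    profile.background = background
    return [
        Interval(profile.genome_id, s, e, label=f"island_{i + 1}")
        for i, (s, e) in enumerate(islands)
    ]


# ---------------------------------------------------------------------------
# Junction evidence


def _near(pos: int, anchor: int, window: int) -> bool:
    return abs(pos - anchor) <= window


def collect_junction_evidence(
    alignments: Iterable[AlignmentRecord],
    candidate: Interval,
    search_window_bp: int = SEARCH_WINDOW_BP,
    max_insert_bp: int = MAX_INSERT_BP,
    min_clip_bp: int = MIN_CLIP_BP,
) -> JunctionEvidence:
    """Gather discordant-pair and split-read evidence at a candidate's edges.

    Pair evidence: one mate within ``search_window_bp`` of the left edge and
    the other within the window of the right edge.  For a circular excised
    template the mates face outward on the linear reference (attL-side mate
    on '-', attR-side mate on '+'); inconsistent orientations are recorded
    with ``orientation_ok=False`` and excluded from the support count.

    Split evidence: alignments clipped by >= ``min_clip_bp`` whose clip
    boundary falls within the window of one edge; the clipped tail of such a
    read continues at the other edge of the circular junction.
    """
    L, R = candidate.start, candidate.end
    w = search_window_bp
    by_read: dict[str, list[AlignmentRecord]] = {}
    splits: list[SplitSupport] = []
    for aln in alignments:
        if aln.genome_id != candidate.genome_id:
            continue
        by_read.setdefault(aln.read_id, []).append(aln)
        if aln.clip_left >= min_clip_bp and _near(aln.pos, L, w):
            partner = aln.mate_pos if aln.mate_pos is not None and _near(aln.mate_pos, R, w) else None
            splits.append(SplitSupport(side="left", clip_pos=aln.pos, partner_pos=partner))
        elif aln.clip_right >= min_clip_bp and _near(aln.end, R, w):
            partner = aln.mate_pos if aln.mate_pos is not None and _near(aln.mate_pos, L, w) else None
            splits.append(SplitSupport(side="right", clip_pos=aln.end, partner_pos=partner))

    pairs: list[PairSupport] = []
    for recs in by_read.values():
        if len(recs) != 2:
            continue
        a, b = sorted(recs, key=lambda r: r.pos)
        # skip pairs that are themselves split at a junction; counted above
        if any(r.clip_left >= min_clip_bp or r.clip_right >= min_clip_bp for r in (a, b)):
            continue
        if _near(a.pos, L, w) and _near(b.end, R, w) and a.pos < b.pos:
            orientation_ok = a.strand == "-" and b.strand == "+"
            pairs.append(
                PairSupport(
                    left_anchor_pos=a.pos,
                    right_anchor_pos=b.pos,
                    orientation_ok=orientation_ok,
                    left_anchor_end=a.end,
                    right_anchor_end=b.end,
                )
            )
    return JunctionEvidence(candidate=candidate, pair_support=pairs, split_support=splits)


# ---------------------------------------------------------------------------
# Boundary refinement


def implied_circular_insert(b_l: int, b_r: int, pair: PairSupport) -> int:
    """Fragment length implied by boundaries (b_l, b_r) for an outward pair.

    On the excised circle the fragment runs from the attR-side mate's start
    to attR, wraps the junction, and ends at the attL-side mate's end:
    (b_r - right_start) + (left_end - b_l).
    """
    return (b_r - pair.right_anchor_pos) + (pair.left_anchor_end - b_l)


def score_boundaries(
    b_l: int, b_r: int, evidence: JunctionEvidence, max_insert_bp: int = MAX_INSERT_BP
) -> tuple[int, int]:
    """(total support, split support) for a boundary pair.

    A pair supports (b_l, b_r) if it is orientation-consistent, both mates
    lie inside the implied prophage, and the implied circular insert is
    positive and <= max_insert_bp.  A split read supports a boundary if its
    clip position equals it exactly.
    """
    n_pairs = 0
    for p in evidence.pair_support:
        if not p.orientation_ok:
            continue
        if b_l <= p.left_anchor_pos and b_r >= p.right_anchor_end:
            ins = implied_circular_insert(b_l, b_r, p)
            if 0 < ins <= max_insert_bp:
                n_pairs += 1
    n_splits = sum(
        1
        for s in evidence.split_support
        if (s.side == "left" and s.clip_pos == b_l)
        or (s.side == "right" and s.clip_pos == b_r)
    )
    return n_pairs + n_splits, n_splits


def _boundary_candidates(
    evidence: JunctionEvidence, search_window_bp: int
) -> tuple[list[int], list[int]]:
    """Candidate attL / attR positions from observed read coordinates.

    The support score only changes at read starts/ends and clip positions,
    so restricting the search to those coordinates (plus the coverage-island
    edges) is exact — exhaustive enumeration agrees (property-tested).  The
    search-window extremes nearest the island interior are included too:
    when one edge has no constraining evidence the score is flat in that
    boundary and the shorter-interval tie-break pushes the optimum to the
    window extreme, which no read coordinate marks.
    """
    cand = evidence.candidate
    w = search_window_bp
    lo_l, hi_l = cand.start - w, cand.start + w
    lo_r, hi_r = cand.end - w, cand.end + w
    lefts = {cand.start, hi_l}
    rights = {cand.end, lo_r}
    for p in evidence.pair_support:
        if p.orientation_ok:
            lefts.add(p.left_anchor_pos)
            rights.add(p.right_anchor_end)
    for s in evidence.split_support:
        (lefts if s.side == "left" else rights).add(s.clip_pos)
    lefts = {x for x in lefts if lo_l <= x <= hi_l}
    rights = {x for x in rights if lo_r <= x <= hi_r}
    return sorted(lefts), sorted(rights)


def refine_boundaries(
    candidate: Interval,
    evidence: JunctionEvidence,
    min_support: int = MIN_SUPPORT,
    search_window_bp: int = SEARCH_WINDOW_BP,
    max_insert_bp: int = MAX_INSERT_BP,
) -> ProphageCall:
    """Choose (attL, attR) maximising junction support.

    Ties are broken by (1) more split-read support, (2) shorter interval,
    (3) leftmost start.  With fewer than ``min_support`` supporting
    observations the call falls back to the coverage-island edges and is
    flagged ``coverage_only`` — the tier the method assigns when read
    coverage is too low to fix boundaries directly.
    """
    lefts, rights = _boundary_candidates(evidence, search_window_bp)
    best: tuple | None = None
    best_pair: tuple[int, int] | None = None
    for b_l in lefts:
        for b_r in rights:
            if b_r <= b_l:
                continue
            total, n_splits = score_boundaries(b_l, b_r, evidence, max_insert_bp)
            key = (total, n_splits, -(b_r - b_l), -b_l)
            if best is None or key > best:
                best = key
                best_pair = (b_l, b_r)
    support = evidence.support_count
    if best is None or best[0] == 0 or support < min_support:
        interval = Interval(candidate.genome_id, candidate.start, candidate.end,
                            label=candidate.label)
        return ProphageCall(interval=interval, support_count=support,
                            confidence="coverage_only")
    b_l, b_r = best_pair
    interval = Interval(candidate.genome_id, b_l, b_r, label=candidate.label)
    confidence = "junction" if support >= min_support else "coverage_only"
    return ProphageCall(interval=interval, support_count=support, confidence=confidence)


def brute_force_boundaries(
    candidate: Interval,
    evidence: JunctionEvidence,
    search_window_bp: int,
    max_insert_bp: int = MAX_INSERT_BP,
) -> tuple[int, int] | None:
    """Exhaustive integer enumeration of boundary pairs (test oracle).

    Scores every (b_l, b_r) with b_l in [start-w, start+w] and b_r in
    [end-w, end+w] using the same objective and tie-breaks as
    `refine_boundaries`.  Quadratic; intended for small windows only.
    """
    best: tuple | None = None
    best_pair: tuple[int, int] | None = None
    for b_l in range(candidate.start - search_window_bp, candidate.start + search_window_bp + 1):
        for b_r in range(candidate.end - search_window_bp, candidate.end + search_window_bp + 1):
            if b_r <= b_l:
                continue
            total, n_splits = score_boundaries(b_l, b_r, evidence, max_insert_bp)
            if total == 0:
                continue
            key = (total, n_splits, -(b_r - b_l), -b_l)
            if best is None or key > best:
                best = key
                best_pair = (b_l, b_r)
    return best_pair


# ---------------------------------------------------------------------------
# Flanking enrichment (lateral transduction signal)


def flanking_enrichment(
    profile: CoverageProfile, call: ProphageCall, window_bp: int
) -> list[FlankReport]:
    """Mean depth, background enrichment and log-depth decay on each flank.

    Lateral transduction packages successive headfuls of chromosome on one
    side of the prophage, producing enrichment >> 1 with a negative decay
    slope (depth falling away from the prophage) on that side only.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    reports: list[FlankReport] = []
    n = profile.length
    for side in ("left", "right"):
        if side == "left":
            lo, hi = max(0, call.interval.start - window_bp), call.interval.start
        else:
            lo, hi = call.interval.end, min(n, call.interval.end + window_bp)
        truncated = (hi - lo) < window_bp
        if truncated:
            logger.warning("flank window truncated at genome end (%s side)", side)
        window = profile.depth[lo:hi]
        if window.size == 0:
            reports.append(FlankReport(call, side, 0, 0.0, 0.0, 0.0, truncated=True))
            continue
        mean_depth = float(window.mean())
        enrichment = mean_depth / profile.background if profile.background > 0 else float("inf")
        # slope of log(depth+1) vs distance from the prophage edge
        x = np.arange(window.size, dtype=float)
        if side == "left":
            x = x[::-1]  # distance increases away from the prophage
        y = np.log(window.astype(float) + 1.0)
        slope = float(np.polyfit(x, y, 1)[0]) if window.size > 1 else 0.0
        reports.append(
            FlankReport(call, side, hi - lo, mean_depth, enrichment, slope, truncated)
        )
    return reports


# ---------------------------------------------------------------------------
# Orchestration


def call_prophages(
    genome: GenomeRecord,
    alignments: Sequence[AlignmentRecord],
    min_fold: float = MIN_FOLD,
    min_len_bp: int = MIN_LEN_BP,
    merge_gap_bp: int = MERGE_GAP_BP,
    search_window_bp: int = SEARCH_WINDOW_BP,
    max_insert_bp: int = MAX_INSERT_BP,
    min_support: int = MIN_SUPPORT,
) -> tuple[list[ProphageCall], CoverageProfile]:
    """Full detection pass: coverage -> islands -> junction refinement.

    Returns the calls (with mean depth and GC relative to the host filled
    in) and the coverage profile with its final background estimate.
    """
    alignments = list(alignments)
    profile = compute_coverage(alignments, genome)
    islands = segment_islands(profile, min_fold, min_len_bp, merge_gap_bp)
    host_gc = genome.gc_fraction()
    calls: list[ProphageCall] = []
    for i, island in enumerate(islands):
        evidence = collect_junction_evidence(
            alignments, island, search_window_bp, max_insert_bp
        )
        call = refine_boundaries(
            island, evidence, min_support, search_window_bp, max_insert_bp
        )
        iv = call.interval
        call.interval = Interval(iv.genome_id, iv.start, iv.end, label=f"prophage_{i + 1}")
        call.mean_depth = profile.mean_depth(iv.start, iv.end)
        region = GenomeRecord(id="region", sequence=genome.sequence[iv.start:iv.end])
        call.gc_relative = region.gc_fraction() - host_gc
        calls.append(call)
    return calls, profile
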