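"""Scoring in-silico prophage predictions against experimentally active ones.

Predictions (e.g. PHASTER or VIBRANT intervals exported to BED/TSV) are
compared to the verified active prophages on three metrics:

* nucleotide precision — fraction of predicted bases inside the active prophage;
* nucleotide recall — fraction of active-prophage bases covered by the prediction;
* active prophage recall — fraction of active prophages "predicted", where a
  prophage counts as predicted only if some single prediction achieves base
  recall strictly greater than a threshold (default 0.75).

Predictions additionally carry structural-gene and insertion-sequence (IS)
annotation flags; `category_rates` tabulates activity by the four
structural x IS cells, the pattern behind IS-mediated prophage inactivation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import Interval

RECALL_THRESHOLD = 0.75


@dataclass(frozen=True)
class PredictionRecord:
    interval: Interval
    tool: str = ""
    confidence_tier: str = "high"  # high / mid / low
    has_structural: bool | None = None  # None = unknown
    has_is: bool | None = None

    def __post_init__(self) -> None:
        if self.confidence_tier not in ("high", "mid", "low"):
            raise ValueError("confidence_tier must be high, mid or low")


@dataclass(frozen=True)
class ComparisonMetrics:
    nucleotide_precision: float
    nucleotide_recall: float
    matched: bool


def nucleotide_precision(pred: Interval, active: Interval) -> float:
    """|pred ∩ active| / |pred|."""
    return pred.intersection_len(active) / pred.length


def nucleotide_recall(pred: Interval, active: Interval) -> float:
    """|pred ∩ active| / |active|."""
    return pred.intersection_len(active) / active.length


def match_predictions(
    preds: Sequence[Interval],
    actives: Sequence[Interval],
    recall_threshold: float = RECALL_THRESHOLD,
) -> dict[Interval, ComparisonMetrics]:
    """Best single-prediction metrics per active prophage.

    An active prophage is matched iff one prediction alone has base recall
    strictly above the threshold; recall is never aggregated across several
    partial predictions.  (A long merged prediction spanning two adjacent
    prophages can legitimately match both.)
    """
    out: dict[Interval, ComparisonMetrics] = {}
    for active in actives:
        best_recall, best_precision = 0.0, 0.0
        for pred in preds:
            r = nucleotide_recall(pred, active)
            if r > best_recall:
                best_recall = r
                best_precision = nucleotide_precision(pred, active)
        out[active] = ComparisonMetrics(
            nucleotide_precision=best_precision,
            nucleotide_recall=best_recall,
            matched=best_recall > recall_threshold,
        )
    return out


def active_prophage_recall(matching: Mapping[Interval, ComparisonMetrics]) -> float:
    """Matched actives / total actives."""
    if not matching:
        raise ValueError("active prophage recall undefined with zero active prophages")
    return sum(m.matched for m in matching.values()) / len(matching)


def category_rates(predictions: Sequence[PredictionRecord],
                   active_flags: Sequence[bool]) -> pd.DataFrame:
    """Activity rate per structural x IS annotation cell.

    Returns a DataFrame with one row per cell (plus an ``unknown`` row for
    predictions with unresolved flags, which are excluded from the cells);
    ``active_fraction`` is NaN, not 0, for empty cells.
    """
    if len(predictions) != len(active_flags):
        raise ValueError("predictions and active flags must align")
    rows = []
    cells = [(True, True), (True, False), (False, True), (False, False)]
    for has_structural, has_is in cells:
        members = [
            act
            for p, act in zip(predictions, active_flags)
            if p.has_structural is has_structural and p.has_is is has_is
        ]
        n, n_active = len(members), sum(members)
        rows.append({
            "has_structural": has_structural,
            "has_is": has_is,
            "n": n,
            "n_active": n_active,
            "active_fraction": (n_active / n) if n else float("nan"),
        })
    n_unknown = sum(p.has_structural is None or p.has_is is None for p in predictions)
    rows.append({
        "has_structural": None, "has_is": None,
        "n": n_unknown, "n_active": 0, "active_fraction": float("nan"),
    })
    return pd.DataFrame(rows)


def metrics_table(
    preds: Sequence[Interval],
    actives: Sequence[Interval],
    recall_threshold: float = RECALL_THRESHOLD,
) -> pd.DataFrame:
    """Per-active metrics as a tidy table (full precision; 1-based coords)."""
    matching = match_predictions(preds, actives, recall_threshold)
    rows = []
    for active, m in matching.items():
        rows.append({
            "genome_id": active.genome_id,
            "start_1based": active.start + 1,
            "end_1based": active.end,
            "label": active.label,
            "best_nucleotide_recall": m.nucleotide_recall,
            "best_nucleotide_precision": m.nucleotide_precision,
            "matched": m.matched,
        })
    return pd.DataFrame(rows)
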