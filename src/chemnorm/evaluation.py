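"""Gold-standard evaluation of normalization output.

Three quantities per cosine threshold τ:

* **overall accuracy** — fraction of gold mentions whose chosen entity
  equals the gold entity, where an abstention (``NONE``) on a mention that
  truly has no lexicon entity counts as correct;
* **disambiguation accuracy** — the same fraction restricted to mentions
  that actually went through the disambiguator;
* **existence classification** — precision/recall/F1 of the binary task
  "does any lexicon entity exist for this mention", with positive
  predictions being non-``NONE`` results after thresholding. Exact-tier
  results bypass the threshold and are always predicted positive.

τ = −1 denotes the unthresholded pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .disambiguator import NONE, NormalizationResult, apply_threshold

__all__ = ["GoldRecord", "EvalReport", "evaluate", "threshold_sweep_table",
           "read_gold_tsv"]


@dataclass(frozen=True)
class GoldRecord:
    doc_id: str
    span: tuple[int, int]
    surface: str
    gold_entity_id: str  # accession or NONE (no entity exists for the mention)


@dataclass
class ThresholdMetrics:
    tau: float
    overall_accuracy: float
    disambiguation_accuracy: float
    existence_precision: float
    existence_recall: float
    existence_f1: float
    n_total: int
    n_disambiguated: int
    n_flagged: int
    n_predicted_positive: int


@dataclass
class EvalReport:
    per_threshold: list[ThresholdMetrics] = field(default_factory=list)

    def at(self, tau: float) -> ThresholdMetrics:
        for m in self.per_threshold:
            if m.tau == tau:
                return m
        raise KeyError(tau)


def read_gold_tsv(path: str | Path) -> list[GoldRecord]:
    """Read a gold standard from 5-column TSV:
    doc_id, start, end, surface, gold_entity_id (or NONE)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            doc_id, start, end, surface, gold = row[:5]
            out.append(GoldRecord(doc_id, (int(start), int(end)), surface, gold))
    return out


def _align(
    results: Sequence[NormalizationResult], gold: Sequence[GoldRecord]
) -> list[tuple[NormalizationResult, GoldRecord]]:
    by_key = {(r.mention.doc_id, r.mention.span): r for r in results}
    pairs = []
    missing = []
    for g in gold:
        r = by_key.get((g.doc_id, g.span))
        if r is None:
            missing.append((g.doc_id, g.span))
        else:
            pairs.append((r, g))
    if missing:
        raise ValueError(f"gold records with no matching result: {missing}")
    return pairs


def evaluate(
    results: Sequence[NormalizationResult],
    gold: Sequence[GoldRecord],
    taus: Iterable[float] = (-1.0,),
) -> EvalReport:
    """Score results against gold at each threshold.

    Results are aligned to gold records by (doc_id, span); a gold record
    with no matching result is a fatal alignment error. Metrics are
    invariant to input ordering.
    """
    pairs = _align(results, gold)
    report = EvalReport()
    for tau in taus:
        thresholded = [(apply_threshold(r, tau), g) for r, g in pairs]
        n_total = len(thresholded)
        correct = sum(1 for r, g in thresholded if r.entity_id == g.gold_entity_id)
        disamb = [(r, g) for r, g in thresholded if r.needs_disambiguation]
        disamb_correct = sum(1 for r, g in disamb if r.entity_id == g.gold_entity_id)
        y_true = [g.gold_entity_id != NONE for _, g in thresholded]
        y_pred = [r.entity_id != NONE for r, _ in thresholded]
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", zero_division=0
        )
        report.per_threshold.append(
            ThresholdMetrics(
                tau=tau,
                overall_accuracy=correct / n_total if n_total else 0.0,
                disambiguation_accuracy=(disamb_correct / len(disamb)) if disamb else 0.0,
                existence_precision=float(precision),
                existence_recall=float(recall),
                existence_f1=float(f1),
                n_total=n_total,
                n_disambiguated=len(disamb),
                n_flagged=sum(1 for r, _ in thresholded if r.flagged_below_threshold),
                n_predicted_positive=sum(y_pred),
            )
        )
    return report


def threshold_sweep_table(report: EvalReport) -> pd.DataFrame:
    """One row per threshold with every metric — the sweep-plot input."""
    return pd.DataFrame(
        [
            {
                "tau": m.tau,
                "overall_accuracy": m.overall_accuracy,
                "disambiguation_accuracy": m.disambiguation_accuracy,
                "existence_precision": m.existence_precision,
                "existence_recall": m.existence_recall,
                "existence_f1": m.existence_f1,
                "n_total": m.n_total,
                "n_disambiguated": m.n_disambiguated,
                "n_flagged": m.n_flagged,
                "n_predicted_positive": m.n_predicted_positive,
            }
            for m in report.per_threshold
        ]
    )
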