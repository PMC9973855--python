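"""Benchmark arithmetic: predicted vs manually curated transporter sets.

Concordance between a predicted transporter id set and a gold-standard
(manual) set: confirmed = intersection, false positives = predicted-only
(rate over the predicted count), false negatives = manual-only (rate over
the manual count). Substrate corrections count confirmed proteins whose
predicted specific substrate disagrees with the gold substrate; an
abstained prediction is never a correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .annotate import Annotation
from .io import MISSING, ParseError
from .rules import STATUS_RETAINED


@dataclass(frozen=True)
class GoldStandard:
    """Manually curated transporter list: id -> optional gold substrate."""

    entries: Mapping[str, str | None]

    @property
    def ids(self) -> set[str]:
        return set(self.entries)


@dataclass(frozen=True)
class EvaluationReport:
    n_predicted: int
    n_manual: int
    n_confirmed: int
    fp: int
    fn: int
    fp_pct: float
    fn_pct: float
    substrate_corrections: int | None = None

    def __post_init__(self):
        if self.fp != self.n_predicted - self.n_confirmed or self.fp < 0:
            raise ValueError("fp must equal n_predicted - n_confirmed and be >= 0")
        if self.fn != self.n_manual - self.n_confirmed or self.fn < 0:
            raise ValueError("fn must equal n_manual - n_confirmed and be >= 0")


def compare_sets(predicted_ids: Iterable[str], gold: GoldStandard) -> EvaluationReport:
    """Concordance counts and rates between prediction and gold standard."""
    predicted = set(predicted_ids)
    manual = gold.ids
    confirmed = predicted & manual
    fp = len(predicted) - len(confirmed)
    fn = len(manual) - len(confirmed)
    return EvaluationReport(
        n_predicted=len(predicted),
        n_manual=len(manual),
        n_confirmed=len(confirmed),
        fp=fp,
        fn=fn,
        fp_pct=100.0 * fp / len(predicted) if predicted else 0.0,
        fn_pct=100.0 * fn / len(manual) if manual else 0.0,
    )


def _norm(substrate: str) -> str:
    return substrate.strip().casefold()


def substrate_corrections(predictions: Iterable[Annotation], gold: GoldStandard) -> int:
    """Confirmed proteins whose predicted specific substrate needs correcting.

    Counted only where a specific substrate was predicted for a confirmed
    protein, the gold standard records a substrate, and the two differ
    after normalization (case-fold, whitespace trim). Abstentions never
    count.
    """
    count = 0
    for ann in predictions:
        if ann.status != STATUS_RETAINED or ann.substrate is None:
            continue
        gold_substrate = gold.entries.get(ann.protein_id)
        if gold_substrate is None:
            continue
        if _norm(ann.substrate) != _norm(gold_substrate):
            count += 1
    return count


def evaluate_annotations(
    predictions: Iterable[Annotation], gold: GoldStandard
) -> EvaluationReport:
    """Full report for a pipeline run: set concordance + substrate corrections."""
    predictions = list(predictions)
    retained = [a.protein_id for a in predictions if a.status == STATUS_RETAINED]
    report = compare_sets(retained, gold)
    return EvaluationReport(
        n_predicted=report.n_predicted,
        n_manual=report.n_manual,
        n_confirmed=report.n_confirmed,
        fp=report.fp,
        fn=report.fn,
        fp_pct=report.fp_pct,
        fn_pct=report.fn_pct,
        substrate_corrections=substrate_corrections(predictions, gold),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def format_report(report: EvaluationReport) -> str:
    """Human-readable report; FP rate to the nearest integer percent, FN
    rate to one decimal."""
    lines = [
        f"Predicted transporters   {report.n_predicted}",
        f"Manual annotation        {report.n_manual}",
        f"Confirmed (overlap)      {report.n_confirmed}",
        f"False positives          {report.fp} ({_round_half_up(report.fp_pct)}%)",
        f"False negatives          {report.fn} ({report.fn_pct:.1f}%)",
    ]
    if report.substrate_corrections is not None:
        lines.append(f"Substrate corrections    {report.substrate_corrections}")
    return "\n".join(lines)


def report_to_tsv(report: EvaluationReport) -> str:
    """Machine-readable single-record TSV of the report."""
    cols = [
        "n_predicted", "n_manual", "n_confirmed",
        "fp", "fn", "fp_pct", "fn_pct", "substrate_corrections",
    ]
    vals = [
        str(report.n_predicted), str(report.n_manual), str(report.n_confirmed),
        str(report.fp), str(report.fn),
        str(_round_half_up(report.fp_pct)), f"{report.fn_pct:.1f}",
        MISSING if report.substrate_corrections is None else str(report.substrate_corrections),
    ]
    return "\t".join(cols) + "\n" + "\t".join(vals) + "\n"


def read_gold_standard(path) -> GoldStandard:
    """Read the gold-standard TSV (header: protein_id, substrate; ``-`` allowed)."""
    path = Path(path)
    entries: dict[str, str | None] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if [h.strip() for h in header] != ["protein_id", "substrate"]:
            raise ParseError(path, 1, f"expected header ['protein_id', 'substrate'], got {header}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(path, lineno, "expected 2 columns")
            pid = fields[0].strip()
            if pid in entries:
                raise ParseError(path, lineno, f"duplicate gold-standard id {pid!r}")
            substrate = fields[1].strip()
            entries[pid] = None if substrate in ("", MISSING) else substrate
    return GoldStandard(entries=entries)


def write_gold_standard(gold: GoldStandard, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsubstrate\n")
        for pid, substrate in gold.entries.items():
            fh.write(f"{pid}\t{substrate if substrate is not None else MISSING}\n")
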