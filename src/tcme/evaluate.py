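"""Scoring pipeline output against the simulation truth ledger.

Planted copies are matched to recovered elements by reciprocal interval
overlap (an element matches a ledger record when it covers more than half
of the planted interval).  The metrics quantify how faithfully the miner
recovers what the generator planted: detection rate, subgroup and
completeness call accuracy, boundary coordinate error on full elements,
and the decay-rule hit rate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import Element
from .synth import TruthLedger, TruthRecord


@dataclass
class RecoveryMetrics:
    n_planted: int
    n_detected: int
    detection_rate_pct: float
    subgroup_accuracy_pct: float        # over matched, non-decay records
    completeness_accuracy_pct: float    # over matched, non-decay records
    boundary_within_5_pct: float        # truth-full records, both ends
    boundary_exact_pct: float
    boundary_mae_nt: float              # mean of max(|ds|, |de|)
    decay_detection_pct: float          # truth decay records called decay
    n_false_loci: int                   # elements matching no planted copy

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def match_to_ledger(elements: list[Element],
                    ledger: TruthLedger) -> list[tuple[TruthRecord, Element | None]]:
    """Greedy best-overlap matching of ledger records to elements."""
    by_key: dict[tuple[str, str], list[Element]] = {}
    for e in elements:
        by_key.setdefault((e.genome_id, e.contig_id), []).append(e)
    pairs: list[tuple[TruthRecord, Element | None]] = []
    used: set[int] = set()
    for r in ledger:
        best: tuple[float, Element] | None = None
        for e in by_key.get((r.genome_id, r.contig_id), []):
            if id(e) in used:
                continue
            ov = min(e.end, r.end) - max(e.start, r.start)
            if ov > 0.5 * (r.end - r.start) and (best is None or ov > best[0]):
                best = (ov, e)
        if best is not None:
            used.add(id(best[1]))
            pairs.append((r, best[1]))
        else:
            pairs.append((r, None))
    return pairs


def recovery_metrics(elements: list[Element], ledger: TruthLedger) -> RecoveryMetrics:
    pairs = match_to_ledger(elements, ledger)
    matched = [(r, e) for r, e in pairs if e is not None]
    n_planted = len(pairs)
    n_detected = len(matched)

    regular = [(r, e) for r, e in matched if r.completeness != "decay"]
    decay = [(r, e) for r, e in matched if r.completeness == "decay"]
    # undetected decay/regular records count as failures of their metric
    n_decay_planted = sum(1 for r, _ in pairs if r.completeness == "decay")

    sub_ok = sum(1 for r, e in regular if e.subgroup == r.subgroup)
    comp_ok = sum(1 for r, e in regular if e.completeness == r.completeness)
    full = [(r, e) for r, e in regular if r.completeness == "full"]
    errs = [max(abs(e.start - r.start), abs(e.end - r.end)) for r, e in full]
    within5 = sum(1 for x in errs if x <= 5)
    exact = sum(1 for x in errs if x == 0)
    decay_ok = sum(1 for r, e in decay if e.group == "decay")

    matched_ids = {id(e) for _, e in matched}
    false_loci = sum(1 for e in elements if id(e) not in matched_ids)

    def pct(a, b):
        return 100.0 * a / b if b else float("nan")

    return RecoveryMetrics(
        n_planted=n_planted,
        n_detected=n_detected,
        detection_rate_pct=pct(n_detected, n_planted),
        subgroup_accuracy_pct=pct(sub_ok, len(regular)),
        completeness_accuracy_pct=pct(comp_ok, len(regular)),
        boundary_within_5_pct=pct(within5, len(full)),
        boundary_exact_pct=pct(exact, len(full)),
        boundary_mae_nt=(sum(errs) / len(errs)) if errs else float("nan"),
        decay_detection_pct=pct(decay_ok, n_decay_planted),
        n_false_loci=false_loci)
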