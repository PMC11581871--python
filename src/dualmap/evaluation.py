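"""Truth-aware labeling of assignment outcomes and confusion-matrix metrics.

Every assignment event has two names, one per reference: a host read correctly
captured in step 1 of a host-first sequential run is a true positive for the
host reference (``S-TP_h1``) and, simultaneously, a true negative for the
parasite reference (``S-TN_p1``).  The label pair is stored explicitly so the
dualities (host FP = parasite FN, and so on) hold by construction and are
still re-checked when tallying.

Read pairs mapped in no genome at all are ``UNMAPPED_BOTH`` and sit outside
the four confusion cells: precision/sensitivity/specificity/accuracy measure
the quality of the reads that *were* separated, not mapping completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DataError
from .strategy import (AssignmentOutcome, Category, HOST_CATEGORIES, Order,
                       PARASITE_CATEGORIES, Strategy)
from .synthetic_data import HOST, PARASITE

UNMAPPED_BOTH = "UNMAPPED_BOTH"
#: sentinel used when two-side reads are kept out of the confusion cells
TWO_SIDE_EXCLUDED = "TWO_SIDE_EXCLUDED"


@dataclass(frozen=True)
class AssignmentLabel:
    """The two reference-specific names of one assignment event.  The numeric
    suffix of sequential labels records the mapping step (1 or 2) at which the
    read was assigned."""

    read_id: str
    strategy: Strategy
    order: Order
    host_label: str
    parasite_label: str


@dataclass(frozen=True)
class ConfusionCounts:
    organism: str
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    """The four separation metrics; an undefined ratio (0/0) is ``None``
    (reported as missing, never coerced to 0 or 1)."""

    precision: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def _sequential_labels(outcome: AssignmentOutcome, origin: str
                       ) -> tuple[str, str]:
    cat = outcome.category
    if cat == Category.UNMAPPED:
        return UNMAPPED_BOTH, UNMAPPED_BOTH
    assigned_host = cat in HOST_CATEGORIES
    if outcome.order == Order.HOST_FIRST:
        step = 1 if assigned_host else 2
    else:
        step = 1 if not assigned_host else 2
    if assigned_host:
        if origin == HOST:     # correct: TP for host, TN for parasite
            return f"S-TP_h{step}", f"S-TN_p{step}"
        return f"S-FP_h{step}", f"S-FN_p{step}"
    if origin == PARASITE:     # correct: TN for host, TP for parasite
        return f"S-TN_h{step}", f"S-TP_p{step}"
    return f"S-FN_h{step}", f"S-FP_p{step}"


def _combined_labels(outcome: AssignmentOutcome, origin: str,
                     two_side_as_error: bool) -> tuple[str, str]:
    cat = outcome.category
    if cat == Category.UNMAPPED:
        return UNMAPPED_BOTH, UNMAPPED_BOTH
    if cat == Category.TWO_SIDE and not two_side_as_error:
        return TWO_SIDE_EXCLUDED, TWO_SIDE_EXCLUDED
    if origin == HOST:
        # TWO_SIDE means the read also reached the wrong genome: by default an
        # error for its origin organism (FN) and an FP for the other
        if cat in HOST_CATEGORIES:
            return "C-TP_h", "C-TN_p"
        return "C-FN_h", "C-FP_p"
    if cat in PARASITE_CATEGORIES:
        return "C-TN_h", "C-TP_p"
    return "C-FP_h", "C-FN_p"


def label_assignments(outcomes: list[AssignmentOutcome],
                      truth: dict[str, str],
                      two_side_as_error: bool = True) -> list[AssignmentLabel]:
    """Attach the reference-specific label pair to every outcome.

    ``truth`` maps read_id to the origin organism; every read must be present.
    ``two_side_as_error`` is the single switch deciding whether a combined-run
    two-side read counts as FN/FP (default) or stays outside the confusion
    cells like the wholly unmapped reads.
    """
    labels: list[AssignmentLabel] = []
    for outcome in outcomes:
        origin = truth.get(outcome.read_id)
        if origin is None:
            raise DataError(f"read {outcome.read_id!r} missing from truth map")
        if origin not in (HOST, PARASITE):
            raise DataError(f"read {outcome.read_id!r}: unknown origin {origin!r}")
        if outcome.strategy == Strategy.SEQUENTIAL:
            h, p = _sequential_labels(outcome, origin)
        else:
            h, p = _combined_labels(outcome, origin, two_side_as_error)
        labels.append(AssignmentLabel(read_id=outcome.read_id,
                                      strategy=outcome.strategy,
                                      order=outcome.order,
                                      host_label=h, parasite_label=p))
    return labels


def _tally(labels: list[AssignmentLabel], side: str) -> dict[str, int]:
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for lab in labels:
        name = lab.host_label if side == HOST else lab.parasite_label
        if name in (UNMAPPED_BOTH, TWO_SIDE_EXCLUDED):
            continue
        kind = name.split("-", 1)[1][:2]  # e.g. "S-TP_h1" -> "TP"
        counts[kind] += 1
    return counts


def confusion_counts(labels: list[AssignmentLabel], organism: str) -> ConfusionCounts:
    """Aggregate one run's labels into TP/FP/TN/FN for one reference.

    All labels must come from a single (strategy, order) run.  Wholly unmapped
    reads are excluded from every cell.  The cross-reference dualities
    (TP_host = TN_parasite, FP_host = FN_parasite) are verified.
    """
    if organism not in (HOST, PARASITE):
        raise ConfigurationError(f"unknown organism {organism!r}")
    runs = {(lab.strategy, lab.order) for lab in labels}
    if len(runs) > 1:
        raise DataError(f"labels mix several runs: {sorted(r for r in runs)}")
    mine = _tally(labels, organism)
    other = _tally(labels, PARASITE if organism == HOST else HOST)
    if mine["TP"] != other["TN"] or mine["FP"] != other["FN"]:
        raise DataError("label duality violated: TP/TN or FP/FN mismatch "
                        f"between references ({mine} vs {other})")
    return ConfusionCounts(organism=organism, TP=mine["TP"], FP=mine["FP"],
                           TN=mine["TN"], FN=mine["FN"])


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """precision=TP/(TP+FP), sensitivity=TP/(TP+FN), specificity=TN/(TN+FP),
    accuracy=(TP+TN)/total; 0/0 ratios are missing."""
    return MetricSet(
        precision=_ratio(counts.TP, counts.TP + counts.FP),
        sensitivity=_ratio(counts.TP, counts.TP + counts.FN),
        specificity=_ratio(counts.TN, counts.TN + counts.FP),
        accuracy=_ratio(counts.TP + counts.TN, counts.total),
    )


def evaluate_run(outcomes: list[AssignmentOutcome], truth: dict[str, str]
                 ) -> dict[str, MetricSet]:
    """Convenience: labels -> confusion counts -> metrics for both organisms."""
    labels = label_assignments(outcomes, truth)
    return {org: compute_metrics(confusion_counts(labels, org))
            for org in (HOST, PARASITE)}
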