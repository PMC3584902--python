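"""Ensemble integration of calibrated component predictions.

For one target, predictions from all component methods are merged per
GO term with the attenuated noisy-OR

    P' = 1 - prod_i (1 - alpha * P_i),

where alpha in [0, 1] (default 0.9) prevents a single confident vote
from asserting certainty.  Scores of deeper (more specific) terms are
then propagated up to their predicted ancestors on the same root path
(using the signed depth difference over the GO graph), mutually
incompatible term pairs — ancestor-related pairs never observed to
co-occur in the annotation corpus — are pruned by deleting the
lower-precision member, and the survivors are ranked by precision.

Both the propagation and the deletion pass evaluate every pair against
a snapshot of the pre-pass precision vector, making the result
independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

from gopred.ontology import GoDag

DEFAULT_ALPHA = 0.9
DEFAULT_FLOOR = 0.01


class Prediction(NamedTuple):
    """One (target, GO term) prediction from one component method."""

    target: str
    term: str
    raw_score: float
    precision: float
    method: str = ""


@dataclass
class CombinedSet:
    """Per-target combined precisions with method provenance."""

    target: str
    precisions: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, set[str]] = field(default_factory=dict)


def combine(
    predictions: Sequence[Prediction],
    alpha: float = DEFAULT_ALPHA,
) -> CombinedSet:
    """Attenuated noisy-OR combination of one target's predictions.

    All predictions must share one target.  No ancestor expansion is
    applied at this stage: only terms some component actually predicted
    enter the combined set.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    targets = {p.target for p in predictions}
    if len(targets) > 1:
        raise ValueError(f"predictions span multiple targets: {sorted(targets)}")
    combined = CombinedSet(target=targets.pop() if targets else "")
    for p in predictions:
        if not 0.0 <= p.precision <= 1.0:
            raise ValueError(f"precision outside [0, 1]: {p}")
        survive = 1.0 - combined.precisions.get(p.term, 0.0)
        combined.precisions[p.term] = 1.0 - survive * (1.0 - alpha * p.precision)
        combined.provenance.setdefault(p.term, set()).add(p.method)
    return combined


def propagate_up(dag: GoDag, combined: CombinedSet) -> CombinedSet:
    """Propagate deeper-term scores up to predicted ancestors.

    For each predicted term i, every predicted term j that is deeper
    than i and ancestor-related to it (signed depth difference defined
    and negative for the pair (i, j)) absorbs into i's score:
    P'_i = 1 - (1 - P_i) * prod_j (1 - P_j), all P read from the
    pre-propagation snapshot.  Terms not already predicted are never
    created.
    """
    snapshot = dict(combined.precisions)
    terms = sorted(snapshot)
    updated = dict(snapshot)
    for i in terms:
        survive = 1.0 - snapshot[i]
        for j in terms:
            if j == i:
                continue
            d = dag.depth_difference(i, j)
            if d is not None and d < 0:
                survive *= 1.0 - snapshot[j]
        updated[i] = 1.0 - survive
    return CombinedSet(
        target=combined.target,
        precisions=updated,
        provenance={t: set(v) for t, v in combined.provenance.items()},
    )


def filter_incompatible(
    combined: CombinedSet,
    cooccurring: set[tuple[str, str]],
    dag: GoDag,
) -> list[tuple[str, float]]:
    """Drop mutually incompatible terms and rank the survivors.

    For every pair of predicted terms with a defined depth difference
    that was never seen to co-occur in the corpus, the lower-precision
    member is deleted; on an exact precision tie both are kept.  All
    pairs are judged against the pre-filter precision vector, then the
    deletions are applied at once.  Survivors are returned ranked by
    precision descending (ties broken by term id).
    """
    prec = combined.precisions
    doomed: set[str] = set()
    for s, t in combinations(sorted(prec), 2):
        if dag.depth_difference(s, t) is None:
            continue
        if (s, t) in cooccurring or (t, s) in cooccurring:
            continue
        if prec[s] < prec[t]:
            doomed.add(s)
        elif prec[t] < prec[s]:
            doomed.add(t)
        # equal precisions: both kept
    return sorted(
        ((t, p) for t, p in prec.items() if t not in doomed),
        key=lambda tp: (-tp[1], tp[0]),
    )


def integrate_target(
    predictions: Sequence[Prediction],
    dag: GoDag,
    cooccurring: set[tuple[str, str]],
    alpha: float = DEFAULT_ALPHA,
    floor: float = DEFAULT_FLOOR,
) -> list[tuple[str, float]]:
    """Full post-processing pipeline for one target.

    Combine -> prune precisions below *floor* -> propagate up ->
    incompatibility filter -> ranked (term, precision) list.
    """
    combined = combine(predictions, alpha=alpha)
    combined.precisions = {t: p for t, p in combined.precisions.items() if p >= floor}
    combined.provenance = {t: v for t, v in combined.provenance.items()
                           if t in combined.precisions}
    combined = propagate_up(dag, combined)
    return filter_incompatible(combined, cooccurring, dag)


# ---------------------------------------------------------------------------
# prediction exchange format (CAFA style)
# ---------------------------------------------------------------------------


def write_predictions(predictions: Iterable[Prediction], path) -> None:
    """Write whitespace-separated ``target GO-term confidence`` lines
    (confidence rounded to 2 decimals, as exchanged between tools)."""
    with open(path, "w") as fh:
        for p in predictions:
            fh.write(f"{p.target}\t{p.term}\t{p.precision:.2f}\n")


def read_predictions(path, method: str = "") -> list[Prediction]:
    """Read a CAFA-style prediction file; header/footer lines (AUTHOR,
    MODEL, KEYWORDS, END, ...) are tolerated and skipped."""
    out: list[Prediction] = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) != 3 or not fields[1].startswith("GO:"):
                continue
            try:
                conf = float(fields[2])
            except ValueError:
                continue
            out.append(Prediction(target=fields[0], term=fields[1],
                                  raw_score=conf, precision=conf, method=method))
    return out
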