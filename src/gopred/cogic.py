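"""Prediction evaluation: simGIC, COGIC and precision/recall curves.

simGIC compares two ancestor-closed GO term sets A and B as the
IC-weighted Jaccard ratio

    simGIC(A, B) = sum_{t in A∩B} IC(t) / sum_{t in A∪B} IC(t).

COGIC stratifies a target's predictions by confidence: the subsets P1..P4
of terms with confidence >= 0.75, 0.5, 0.25 and 0 are each
ancestor-expanded and compared to the expanded reference R, and

    COGIC(P, R) = (S1 + S2 + S3 + S4) / 4,  S_k = simGIC(R, P_k),

so correct predictions with higher confidence are rewarded more.  COGIC
is 1 when R = P1 = .. = P4 and 0 when every subset intersects R only at
the namespace root (whose IC is 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from gopred.corpus import IcTable, UndefinedIcError
from gopred.ontology import GoDag

#: COGIC confidence thresholds defining the subsets P1..P4.
COGIC_THRESHOLDS = (0.75, 0.5, 0.25, 0.0)


@dataclass
class EvaluationPair:
    """One target's predictions (term -> confidence) and its experimental
    reference term set, in a single namespace."""

    target: str
    predicted: dict[str, float] = field(default_factory=dict)
    reference: set[str] = field(default_factory=set)


def _ic_lookup(ic: IcTable, term: str, dag: GoDag | None, zero_count_ic: str):
    try:
        return ic.ic[term]
    except KeyError:
        if zero_count_ic == "error" or dag is None:
            raise UndefinedIcError(f"term {term!r} has no propagated count") from None
        # unverifiable specificity: score as the most specific observed term
        return ic.max_ic(dag.namespace[dag.resolve(term)])


def simgic(
    ic: IcTable,
    set_a: Iterable[str],
    set_b: Iterable[str],
    dag: GoDag | None = None,
    zero_count_ic: str = "max",
) -> float:
    """IC-weighted Jaccard similarity of two ancestor-closed term sets.

    Terms with no propagated count (undefined IC) are assigned the
    maximum observed IC in their namespace when ``zero_count_ic="max"``
    (requires *dag*), or raise with ``"error"``.  If the union carries
    zero total IC (both sets within the root), returns 1.0 when the sets
    are equal and 0.0 otherwise.
    """
    A, B = set(set_a), set(set_b)
    if dag is not None:
        spaces = {dag.namespace[dag.resolve(t)] for t in A | B}
        if len(spaces) > 1:
            raise ValueError(f"term sets mix namespaces: {sorted(spaces)}")
    union_ic = sum(_ic_lookup(ic, t, dag, zero_count_ic) for t in A | B)
    if union_ic == 0.0:
        return 1.0 if A == B else 0.0
    inter_ic = sum(_ic_lookup(ic, t, dag, zero_count_ic) for t in A & B)
    return inter_ic / union_ic


def confidence_subsets(
    predicted: Mapping[str, float],
    dag: GoDag,
    thresholds: Sequence[float] = COGIC_THRESHOLDS,
) -> list[set[str]]:
    """Ancestor-expanded confidence-stratified prediction subsets P1..P4.

    P_k holds the terms with confidence >= thresholds[k-1] (boundary
    values included), each expanded with all ancestral nodes.
    """
    for term, conf in predicted.items():
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"confidence outside [0, 1] for {term}: {conf}")
    return [
        dag.expand(t for t, c in predicted.items() if c >= tau)
        for tau in thresholds
    ]


def cogic_score(
    ic: IcTable,
    dag: GoDag,
    pair: EvaluationPair,
    zero_count_ic: str = "max",
) -> float:
    """COGIC score for one target: mean of the four stratified simGIC values."""
    if not pair.reference:
        raise ValueError(f"target {pair.target}: empty reference set")
    reference = dag.expand(pair.reference)
    subsets = confidence_subsets(pair.predicted, dag)
    scores = [simgic(ic, reference, p_k, dag=dag, zero_count_ic=zero_count_ic)
              for p_k in subsets]
    return sum(scores) / len(scores)


def precision_recall_curve(
    dag: GoDag,
    pairs: Sequence[EvaluationPair],
    thresholds: Sequence[float],
) -> list[tuple[float, float, float]]:
    """Average term-level precision and recall across targets.

    Per threshold tau and target: the predicted set is the
    ancestor-expanded terms with confidence >= tau and the reference is
    the ancestor-expanded annotation set, both with the namespace root
    excluded; precision = |pred ∩ ref| / |pred| (targets with an empty
    predicted set are skipped for precision), recall = |pred ∩ ref| /
    |ref|.  Returns (threshold, mean precision, mean recall) rows.
    """
    if not pairs:
        raise ValueError("need at least one evaluation pair")
    roots = set(dag.root.values())
    curve = []
    for tau in thresholds:
        precisions, recalls = [], []
        for pair in pairs:
            ref = dag.expand(pair.reference) - roots
            pred = dag.expand(
                t for t, c in pair.predicted.items() if c >= tau
            ) - roots
            hit = len(pred & ref)
            if pred:
                precisions.append(hit / len(pred))
            recalls.append(hit / len(ref) if ref else 0.0)
        curve.append((
            tau,
            sum(precisions) / len(precisions) if precisions else 0.0,
            sum(recalls) / len(recalls),
        ))
    return curve
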