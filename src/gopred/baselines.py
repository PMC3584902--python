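"""Naive comparator predictors.

Two floors against which the integrative method is judged:

* **Priors**: assigns the k most frequent GO terms (by ancestor-expanded
  annotation frequency) to every target, with the frequency itself as
  confidence — completely target-independent.
* **BLAST**: transfers the GO terms of experimentally annotated hit
  subjects, with confidence equal to the best supporting hit's sequence
  identity scaled to [0, 1].
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from gopred.corpus import AnnotationCorpus, term_counts
from gopred.ensemble import Prediction
from gopred.homology import HomologyHit
from gopred.ontology import GoDag

logger = logging.getLogger(__name__)

DEFAULT_PRIORS_K = 10_000


def priors_predictor(
    corpus: AnnotationCorpus,
    dag: GoDag,
    targets: Sequence[str],
    k: int = DEFAULT_PRIORS_K,
) -> list[Prediction]:
    """Frequency-prior predictor: the identical top-k term list for all.

    Term confidence is its ancestor-expanded annotation frequency
    (propagated count over the namespace root count); the root itself
    scores 1.0.  If *k* exceeds the annotated vocabulary, all terms are
    returned with a warning.
    """
    if not corpus.records:
        raise ValueError("corpus is empty")
    table = term_counts(corpus, dag)
    freqs = {
        t: n / table.root_count[table.namespace[t]]
        for t, n in table.counts.items()
    }
    if k > len(freqs):
        logger.warning("k=%d exceeds vocabulary of %d terms", k, len(freqs))
    top = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return [
        Prediction(target=target, term=t, raw_score=f, precision=f, method="priors")
        for target in targets
        for t, f in top
    ]


def blast_baseline(
    hits: Iterable[HomologyHit],
    annotations: AnnotationCorpus,
) -> list[Prediction]:
    """Identity-weighted homology transfer baseline.

    Every term of every annotated hit subject is transferred; per
    (target, term) the confidence is the maximum percent identity over
    supporting hits, scaled to [0, 1].
    """
    subject_terms = annotations.by_protein()
    best: dict[tuple[str, str], float] = {}
    for hit in hits:
        for term in subject_terms.get(hit.subject, ()):
            key = (hit.target, term)
            ident = hit.percent_identity / 100.0
            if ident > best.get(key, -1.0):
                best[key] = ident
    return [
        Prediction(target=t, term=term, raw_score=s, precision=s, method="blast")
        for (t, term), s in sorted(best.items())
    ]
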