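"""Protein annotation corpora, information content and co-occurrence.

An :class:`AnnotationCorpus` holds protein -> GO term annotations with GAF
evidence codes.  From it we derive the two statistics the evaluation and
post-processing layers need:

* ancestor-propagated term counts and the information content
  IC(t) = -log(n(t) / n(r)) (natural log), where n(t) is the number of
  distinct proteins whose true-path-expanded annotation set contains t and
  r is the namespace root;
* the term co-occurrence index: the set of unordered term pairs seen
  together in some protein's expanded annotation set, used by the ensemble
  incompatibility filter.

Counting deduplicates per protein after ancestor expansion, so a protein
contributes at most 1 to any term even when annotated to both a term and
one of its ancestors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple

from Bio.UniProt.GOA import GAF20FIELDS

from gopred.ontology import ASPECT_CODES, GoDag

logger = logging.getLogger(__name__)

#: GO experimental evidence codes (electronic/curated-inference excluded).
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

#: GAF controlled evidence vocabulary (superset incl. non-experimental).
GAF_EVIDENCE_CODES = EXPERIMENTAL_CODES | frozenset({
    "HTP", "HDA", "HMP", "HGI", "HEP",
    "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA",
    "TAS", "NAS", "IC", "ND", "IEA",
})


class AnnotationRecord(NamedTuple):
    protein: str
    term: str
    evidence: str
    namespace: str  # "MF" or "BP"


@dataclass
class AnnotationCorpus:
    """Protein -> GO annotations with evidence codes."""

    records: list[AnnotationRecord] = field(default_factory=list)

    @property
    def proteins(self) -> set[str]:
        return {r.protein for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def by_protein(self, namespace: str | None = None) -> dict[str, set[str]]:
        """Mapping protein -> set of directly annotated terms."""
        out: dict[str, set[str]] = {}
        for r in self.records:
            if namespace is not None and r.namespace != namespace:
                continue
            out.setdefault(r.protein, set()).add(r.term)
        return out

    def terms_for(self, protein: str) -> set[str]:
        return {r.term for r in self.records if r.protein == protein}


class GafError(ValueError):
    """Raised when a GAF file is unusable (too many malformed rows)."""


def read_gaf(path, dag: GoDag) -> AnnotationCorpus:
    """Read a GAF 2.x file into an :class:`AnnotationCorpus`.

    Comment lines are skipped; NOT-qualified rows and cellular_component
    rows are dropped; secondary term ids are resolved through *dag*.
    Malformed rows are skipped with a logged line number; if more than
    half of the data rows are skipped a :class:`GafError` is raised.
    """
    records: list[AnnotationRecord] = []
    n_data = n_skipped = 0
    i_object = GAF20FIELDS.index("DB_Object_ID")
    i_qual = GAF20FIELDS.index("Qualifier")
    i_go = GAF20FIELDS.index("GO_ID")
    i_ev = GAF20FIELDS.index("Evidence")
    i_aspect = GAF20FIELDS.index("Aspect")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            n_data += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= i_aspect or not fields[i_object] or not fields[i_go]:
                logger.warning("%s:%d: malformed GAF row skipped", path, lineno)
                n_skipped += 1
                continue
            qualifier = fields[i_qual]
            if "NOT" in qualifier.split("|"):
                continue
            aspect = ASPECT_CODES.get(fields[i_aspect])
            if aspect not in ("MF", "BP"):
                continue
            term = dag.resolve(fields[i_go])
            if term not in dag:
                logger.warning("%s:%d: unknown term %s skipped", path, lineno, term)
                n_skipped += 1
                continue
            if term in dag.obsolete:
                logger.warning("%s:%d: obsolete term %s dropped", path, lineno, term)
                continue
            records.append(AnnotationRecord(fields[i_object], term, fields[i_ev], aspect))
    if n_data and n_skipped > n_data / 2:
        raise GafError(f"{path}: {n_skipped}/{n_data} rows malformed")
    return AnnotationCorpus(records)


_ASPECT_OUT = {"MF": "F", "BP": "P"}


def write_gaf(corpus: AnnotationCorpus, path) -> None:
    """Write *corpus* as a GAF 2.2 file (fixtures support)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for r in corpus.records:
            fields = [""] * len(GAF20FIELDS)
            fields[0] = "gopred"
            fields[1] = r.protein
            fields[2] = r.protein
            fields[3] = "enables" if r.namespace == "MF" else "involved_in"
            fields[4] = r.term
            fields[5] = "GO_REF:0000000"
            fields[6] = r.evidence
            fields[8] = _ASPECT_OUT[r.namespace]
            fields[11] = "protein"
            fields[12] = "taxon:0"
            fields[13] = "20200101"
            fields[14] = "gopred"
            fh.write("\t".join(fields) + "\n")


def filter_experimental(
    corpus: AnnotationCorpus,
    codes: Iterable[str] = EXPERIMENTAL_CODES,
) -> AnnotationCorpus:
    """Retain only records whose evidence code is in *codes*."""
    codes = frozenset(codes)
    return AnnotationCorpus([r for r in corpus.records if r.evidence in codes])


class UndefinedIcError(KeyError):
    """Information content requested for a term with no propagated count."""


@dataclass
class IcTable:
    """Ancestor-propagated annotation counts and information content.

    ``counts`` maps term -> number of distinct proteins whose expanded
    annotation set contains the term; ``root_count`` gives the root's
    propagated count per namespace; ``ic`` holds -log(n(t)/n(r)) in nats.
    """

    counts: dict[str, int]
    root_count: dict[str, int]
    ic: dict[str, float]
    namespace: dict[str, str]

    def max_ic(self, namespace: str) -> float:
        """Largest observed IC in a namespace (fallback for zero-count terms)."""
        vals = [v for t, v in self.ic.items() if self.namespace[t] == namespace]
        if not vals:
            raise UndefinedIcError(f"no counted terms in namespace {namespace}")
        return max(vals)


def term_counts(corpus: AnnotationCorpus, dag: GoDag) -> IcTable:
    """Ancestor-propagate annotation counts and derive information content.

    Each protein contributes 1 to every term in the union of the ancestor
    closures of its annotated terms, per namespace.  Namespaces with no
    annotations are absent from the table.
    """
    counts: dict[str, int] = {}
    namespace: dict[str, str] = {}
    for ns in ("MF", "BP"):
        for protein, terms in corpus.by_protein(ns).items():
            for t in dag.expand(terms):
                counts[t] = counts.get(t, 0) + 1
                namespace[t] = ns
    root_count = {
        ns: counts[root] for ns, root in dag.root.items() if root in counts
    }
    ic = {
        t: -math.log(n / root_count[namespace[t]])
        for t, n in counts.items()
    }
    return IcTable(counts=counts, root_count=root_count, ic=ic, namespace=namespace)


def information_content(ic_table: IcTable, term: str) -> float:
    """IC(t) = -log(n(t)/n(r)); raises :class:`UndefinedIcError` when the
    term has no propagated count."""
    try:
        return ic_table.ic[term]
    except KeyError:
        raise UndefinedIcError(f"term {term!r} has no propagated count") from None


def cooccurrence_pairs(corpus: AnnotationCorpus, dag: GoDag) -> set[tuple[str, str]]:
    """Unordered term pairs seen together in some protein's expanded set.

    Pairs are returned as sorted 2-tuples; no reflexive (t, t) pairs.
    """
    pairs: set[tuple[str, str]] = set()
    for ns in ("MF", "BP"):
        for protein, terms in corpus.by_protein(ns).items():
            expanded = sorted(dag.expand(terms))
            pairs.update(combinations(expanded, 2))
    return pairs
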