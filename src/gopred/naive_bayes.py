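"""Naive Bayes GO term annotators: record text mining and trigram mining.

Two annotators share one trainer/scorer:

* **Text mining** over Swiss-Prot-style line-typed flat records.  Words
  and adjacent word pairs from descriptive lines become tokens; feature
  (FT) lines get special handling — tokens keep their case with an
  ``FT:`` prefix, and residue numbers are placed into bins of width 50
  and emitted as ``FT:NUMVALk`` tokens.  Token statistics are taken at
  the record level (presence/absence).
* **Trigram mining** over amino-acid sequences: every overlapping
  3-letter window is a token, counted with multiplicity.

For a term G and token w, with f(w|G) and f(w|~G) the pseudocount-
smoothed token frequencies among records annotated / not annotated with
G, the per-token posterior is p(G|w) = f(w|G) / (f(w|G) + f(w|~G)); a
document's raw score for G is the sum of per-token log-odds
log p - log(1 - p).  Raw scores are later mapped to precisions by the
calibration module — they are never read as probabilities directly.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: flat-record line types consumed by the text annotator
DEFAULT_LINE_TYPES = ("DE", "CC", "KW", "FT")

#: width of the residue-number bins on FT lines
NUMVAL_BIN_WIDTH = 50

_WORD_RE = re.compile(r"[a-z0-9]+")
_FT_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+")


@dataclass
class TokenDocument:
    """Ordered token list for one protein (words, FT tokens or trigrams)."""

    protein: str
    tokens: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)


def _text_tokens(content: str) -> list[str]:
    """Lowercased unigrams plus adjacent-pair bigrams from one line."""
    words = _WORD_RE.findall(content.lower())
    return words + [f"{a}_{b}" for a, b in zip(words, words[1:])]


def _ft_tokens(content: str) -> list[str]:
    """FT-line tokens: case kept, ``FT:`` prefix, integers -> width-50 bins.

    Range endpoints are binned independently.
    """
    out = []
    for tok in _FT_TOKEN_RE.findall(content):
        if tok.isdigit():
            out.append(f"FT:NUMVAL{int(tok) // NUMVAL_BIN_WIDTH}")
        else:
            out.append(f"FT:{tok}")
    return out


def tokenize_record(
    record_text: str,
    protein: str = "",
    line_types: Iterable[str] = DEFAULT_LINE_TYPES,
) -> TokenDocument:
    """Tokenize a Swiss-Prot-style line-typed flat-file entry.

    Each line starts with a two-letter line-type code.  Descriptive lines
    (DE/CC/KW by default) yield lowercased unigrams and adjacent bigrams;
    FT lines yield case-preserving ``FT:``-prefixed tokens with residue
    numbers mapped to ``FT:NUMVALk``, k = floor(value / 50).
    """
    wanted = set(line_types)
    tokens: list[str] = []
    for line in record_text.splitlines():
        code, _, content = line.partition(" ")
        code = code.strip()
        if code not in wanted:
            continue
        if code == "FT":
            tokens.extend(_ft_tokens(content))
        else:
            tokens.extend(_text_tokens(content))
    return TokenDocument(protein=protein, tokens=tokens)


def trigram_tokens(sequence: str, protein: str = "") -> TokenDocument:
    """All overlapping amino-acid trigrams of *sequence*, in order.

    Letters outside the 20-residue alphabet are mapped to ``X``.  A
    sequence shorter than 3 yields an empty document (with a warning).
    """
    seq = "".join(c if c in AMINO_ACIDS else "X" for c in sequence.upper())
    if len(seq) < 3:
        logger.warning("sequence of length %d yields no trigrams", len(seq))
        return TokenDocument(protein=protein, tokens=[])
    return TokenDocument(
        protein=protein,
        tokens=[seq[i:i + 3] for i in range(len(seq) - 2)],
    )


@dataclass
class NbModel:
    """Per-term smoothed token posteriors p(GO|token).

    ``token_p[term]`` maps each vocabulary token to its smoothed
    posterior; ``unseen_p[term]`` is the posterior assigned to tokens
    never seen in training (computed from the pseudocount alone), so
    scoring never produces infinities.  ``log_odds`` selects the scoring
    form: log p - log(1-p) (default) or log p only.
    """

    vocabulary: set[str]
    token_p: dict[str, dict[str, float]]
    unseen_p: dict[str, float]
    prior_counts: dict[str, int]
    pseudocount: float = 1.0
    multiplicity: bool = False
    log_odds: bool = True

    @property
    def terms(self) -> set[str]:
        return set(self.token_p)


def train_nb(
    documents: Iterable[TokenDocument],
    labels: Mapping[str, Iterable[str]],
    pseudocount: float = 1.0,
    multiplicity: bool = False,
    log_odds: bool = True,
) -> NbModel:
    """Train the naive Bayes annotator.

    ``labels`` maps protein id -> annotated term set.  For each term with
    at least one positive document, f(token|GO) and f(token|~GO) are the
    pseudocount-smoothed token frequencies in the positive / negative
    document groups: presence/absence per document for text records
    (``multiplicity=False``), raw token counts for trigram mining
    (``multiplicity=True``).  Terms with no positive document are skipped
    with a warning.
    """
    docs = list(documents)
    label_sets = {p: set(ts) for p, ts in labels.items()}
    all_terms = sorted(set().union(*label_sets.values())) if label_sets else []
    vocabulary: set[str] = set()
    for d in docs:
        vocabulary.update(d.tokens)

    # per-document token statistic: multiset or set
    doc_counts: list[dict[str, int]] = []
    doc_totals: list[int] = []
    for d in docs:
        if multiplicity:
            counts: dict[str, int] = {}
            for tok in d.tokens:
                counts[tok] = counts.get(tok, 0) + 1
        else:
            counts = dict.fromkeys(d.tokens, 1)
        doc_counts.append(counts)
        doc_totals.append(sum(counts.values()))

    V = len(vocabulary)
    token_p: dict[str, dict[str, float]] = {}
    unseen_p: dict[str, float] = {}
    prior_counts: dict[str, int] = {}
    for term in all_terms:
        pos_idx = [i for i, d in enumerate(docs)
                   if term in label_sets.get(d.protein, ())]
        neg_idx = [i for i in range(len(docs)) if i not in set(pos_idx)]
        if not pos_idx:
            logger.warning("term %s has no positive documents; skipped", term)
            continue
        prior_counts[term] = len(pos_idx)
        pos_tok: dict[str, int] = {}
        neg_tok: dict[str, int] = {}
        for i in pos_idx:
            for tok, n in doc_counts[i].items():
                pos_tok[tok] = pos_tok.get(tok, 0) + n
        for i in neg_idx:
            for tok, n in doc_counts[i].items():
                neg_tok[tok] = neg_tok.get(tok, 0) + n
        if multiplicity:
            # multinomial smoothing: (count + k) / (total + k*V)
            pos_den = sum(doc_totals[i] for i in pos_idx) + pseudocount * V
            neg_den = sum(doc_totals[i] for i in neg_idx) + pseudocount * V
        else:
            # per-document presence: (docs containing + k) / (docs + 2k)
            pos_den = len(pos_idx) + 2 * pseudocount
            neg_den = len(neg_idx) + 2 * pseudocount
        pd: dict[str, float] = {}
        for tok in vocabulary:
            f_pos = (pos_tok.get(tok, 0) + pseudocount) / pos_den
            f_neg = (neg_tok.get(tok, 0) + pseudocount) / neg_den
            pd[tok] = f_pos / (f_pos + f_neg)
        token_p[term] = pd
        f_pos0 = pseudocount / pos_den
        f_neg0 = pseudocount / neg_den
        unseen_p[term] = f_pos0 / (f_pos0 + f_neg0)
    return NbModel(
        vocabulary=vocabulary, token_p=token_p, unseen_p=unseen_p,
        prior_counts=prior_counts, pseudocount=pseudocount,
        multiplicity=multiplicity, log_odds=log_odds,
    )


def score_terms(model: NbModel, document: TokenDocument) -> dict[str, float]:
    """Raw log-likelihood score of *document* for every trained term.

    Per term, the sum over document tokens of log p(GO|token) minus
    (in log-odds mode) log(1 - p(GO|token)); tokens unseen in training
    use the smoothed unseen posterior.  Returned mapping is sorted by
    descending score.  An empty document yields an empty mapping.
    """
    if not document.tokens:
        return {}
    scores: dict[str, float] = {}
    for term, pd in model.token_p.items():
        s = 0.0
        p0 = model.unseen_p[term]
        for tok in document.tokens:
            p = pd.get(tok, p0)
            s += math.log(p) - (math.log(1.0 - p) if model.log_odds else 0.0)
        scores[term] = s
    return dict(sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])))


def read_flat_records(path) -> list[tuple[str, str]]:
    """Read a Swiss-Prot-style flat file of ``//``-separated entries.

    Each entry's ``ID`` line names the protein; returns a list of
    (protein id, full record text) pairs.
    """
    out: list[tuple[str, str]] = []
    current: list[str] = []
    protein = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("//"):
                if current:
                    out.append((protein, "".join(current)))
                current, protein = [], ""
                continue
            if line.startswith("ID"):
                parts = line.split()
                protein = parts[1] if len(parts) > 1 else ""
            current.append(line)
    if current:
        out.append((protein, "".join(current)))
    return out
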