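"""Homology-based GO transfer.

Three evolutionary routes to annotation transfer:

* **Pairwise hits** (PSI-BLAST style): GO terms of subjects aligned over
  at least 85% of the target's length are transferred; the raw score of
  a (target, term) pair is the highest supporting bit score, converted
  to a precision by the method's calibration model.
* **Orthologous groups**: a target inherits every GO term found on any
  annotated member of its group, with estimated precision equal to the
  fraction of annotated members sharing the term (ancestor-expanded;
  the target itself is excluded from the tally).
* **Profile-profile alignment**: PSSM columns are compared with a
  symmetric normalized cross dot-product of log-odds scores against
  target frequencies, aligned globally under affine gap penalties
  (opening 11, extension 1), and the resulting (score, identity,
  coverage, coverage) feature vector is judged by a small 4-4-1 neural
  network trained per GO term.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from gopred.calibration import CalibrationModel, estimate_precision
from gopred.corpus import AnnotationCorpus
from gopred.ensemble import Prediction
from gopred.ontology import GoDag

#: minimum fraction of the target's length an alignment must cover
COVERAGE_CUTOFF = 0.85

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # PSI-BLAST ASCII PSSM column order


class HomologyHit(NamedTuple):
    """One precomputed search hit between a target and a subject."""

    target: str
    subject: str
    bit_score: float
    percent_identity: float
    target_coverage: float
    subject_coverage: float


def read_hits_table(path) -> list[HomologyHit]:
    """Read BLAST/PSI-BLAST tabular hits (outfmt-6 + qlen/slen columns).

    Expected columns: qseqid sseqid pident length qstart qend sstart
    send evalue bitscore qlen slen.  Coverages are computed from the
    aligned spans divided by the full lengths.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            qstart, qend, sstart, send = (int(f[i]) for i in (4, 5, 6, 7))
            qlen, slen = int(f[10]), int(f[11])
            hits.append(HomologyHit(
                target=f[0], subject=f[1],
                bit_score=float(f[9]), percent_identity=float(f[2]),
                target_coverage=(abs(qend - qstart) + 1) / qlen,
                subject_coverage=(abs(send - sstart) + 1) / slen,
            ))
    return hits


def transfer_from_hits(
    hits: Iterable[HomologyHit],
    annotations: AnnotationCorpus,
    model: CalibrationModel,
    coverage_cutoff: float = COVERAGE_CUTOFF,
) -> list[Prediction]:
    """Transfer subject GO terms to targets through qualifying hits.

    Hits covering less than *coverage_cutoff* of the target's length are
    discarded; for each surviving (target, term) pair the raw score is
    the maximum supporting bit score, calibrated to a precision.
    """
    subject_terms = annotations.by_protein()
    best: dict[tuple[str, str], float] = {}
    for hit in hits:
        if hit.target_coverage < coverage_cutoff:
            continue
        for term in subject_terms.get(hit.subject, ()):
            key = (hit.target, term)
            if hit.bit_score > best.get(key, -np.inf):
                best[key] = hit.bit_score
    return [
        Prediction(target=t, term=term, raw_score=s,
                   precision=estimate_precision(model, s), method=model.method_tag or "homology")
        for (t, term), s in sorted(best.items())
    ]


def read_groups(path) -> dict[str, str]:
    """Read a two-column (protein, group id) orthologous-group file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            protein, group = line.split()[:2]
            out[protein] = group
    return out


def ortho_transfer(
    groups: Mapping[str, str],
    annotations: AnnotationCorpus,
    dag: GoDag,
    targets: Iterable[str] | None = None,
) -> list[Prediction]:
    """Orthologous-group annotation voting.

    ``groups`` maps protein -> group id.  Each target inherits every GO
    term found on an annotated member of its group, with precision =
    (annotated members carrying the term, after ancestor expansion) /
    (annotated members); the target itself never votes.
    """
    members: dict[str, list[str]] = {}
    for protein, group in groups.items():
        members.setdefault(group, []).append(protein)
    expanded: dict[str, set[str]] = {
        p: dag.expand(terms) for p, terms in annotations.by_protein().items()
    }
    out: list[Prediction] = []
    for target in sorted(targets if targets is not None else groups):
        group = groups.get(target)
        if group is None:
            continue
        voters = [p for p in members[group] if p != target and p in expanded]
        if not voters:
            continue
        tally: dict[str, int] = {}
        for p in voters:
            for term in expanded[p]:
                tally[term] = tally.get(term, 0) + 1
        for term in sorted(tally):
            frac = tally[term] / len(voters)
            out.append(Prediction(target=target, term=term, raw_score=frac,
                                  precision=frac, method="orthologs"))
    return out


# ---------------------------------------------------------------------------
# profile-profile alignment
# ---------------------------------------------------------------------------


@dataclass
class Pssm:
    """Position-specific scoring matrix for one sequence profile.

    ``log_odds`` is the (L, 20) matrix of per-position log-odds scores;
    ``target_freq`` the (L, 20) matrix of target frequencies, each row a
    simplex vector (sums to 1 within 1e-6).  Columns follow the
    PSI-BLAST residue order ``ARNDCQEGHILKMFPSTWYV``.
    """

    name: str
    log_odds: np.ndarray
    target_freq: np.ndarray

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.target_freq = np.asarray(self.target_freq, dtype=float)
        if self.log_odds.shape != self.target_freq.shape or self.log_odds.shape[1] != 20:
            raise ValueError("PSSM matrices must both be (L, 20)")
        sums = self.target_freq.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("target-frequency rows must sum to 1")

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        """Most probable residue per position (by target frequency)."""
        return "".join(AA_ORDER[i] for i in np.argmax(self.target_freq, axis=1))


def read_pssm(path) -> Pssm:
    """Read a PSI-BLAST ASCII PSSM (20 log-odds + 20 percentage columns).

    Percentage columns are renormalized to frequencies; all-zero rows
    fall back to the uniform distribution.
    """
    log_odds_rows, freq_rows = [], []
    name = str(path)
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) >= 42 and fields[0].isdigit():
                vals = [float(x) for x in fields[2:42]]
                log_odds_rows.append(vals[:20])
                freq_rows.append(vals[20:])
    if not log_odds_rows:
        raise ValueError(f"{path}: no PSSM rows found")
    freqs = np.asarray(freq_rows, dtype=float)
    sums = freqs.sum(axis=1, keepdims=True)
    uniform = np.full(20, 1.0 / 20)
    freqs = np.where(sums > 0, freqs / np.where(sums == 0, 1, sums), uniform)
    return Pssm(name=name, log_odds=np.asarray(log_odds_rows), target_freq=freqs)


def profile_column_score(
    x: tuple[np.ndarray, np.ndarray], y: tuple[np.ndarray, np.ndarray]
) -> float:
    """Symmetric normalized cross dot-product of two PSSM columns.

    Each argument is a (log-odds 20-vector, target-frequency 20-vector)
    pair; the score is (x_tf . y) / sum(x_tf) + (y_tf . x) / sum(y_tf),
    which for simplex-normalized frequencies reduces to
    x_tf . y + y_tf . x.
    """
    x_lo, x_tf = (np.asarray(v, dtype=float) for v in x)
    y_lo, y_tf = (np.asarray(v, dtype=float) for v in y)
    sx, sy = x_tf.sum(), y_tf.sum()
    if sx == 0 or sy == 0:
        raise ValueError("target-frequency vector sums to zero")
    return float(x_tf @ y_lo / sx + y_tf @ x_lo / sy)


class AlignmentResult(NamedTuple):
    score: float
    pairs: list[tuple[int, int]]  # aligned column index pairs (0-based)
    percent_identity: float
    coverage_a: float
    coverage_b: float


def _column_score_matrix(a: Pssm, b: Pssm) -> np.ndarray:
    sa = a.target_freq.sum(axis=1, keepdims=True)
    sb = b.target_freq.sum(axis=1, keepdims=True)
    return (a.target_freq / sa) @ b.log_odds.T + a.log_odds @ (b.target_freq / sb).T


def align_profiles(
    a: Pssm,
    b: Pssm,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Global profile-profile alignment with affine gap penalties.

    Three-state dynamic programming maximizing summed column scores
    minus gap costs; a gap of length k costs gap_open + (k-1)*gap_extend
    (end gaps are charged).  Identity is computed over aligned columns
    using each profile's consensus residue; coverage is the fraction of
    each profile's columns that are aligned.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("profiles must be non-empty")
    S = _column_score_matrix(a, b)
    la, lb = len(a), len(b)
    NEG = -1e18
    M = np.full((la + 1, lb + 1), NEG)   # a[i-1] aligned to b[j-1]
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in b (a column unmatched)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, lb + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = S[i - 1, j - 1] + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - gap_open)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    score = float([M[i, j], Ix[i, j], Iy[i, j]][state])
    pairs: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            prev = int(np.argmax([M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]))
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            state = int(np.argmax([M[i - 1, j] - gap_open,
                                   Iy[i - 1, j] - gap_open,
                                   Ix[i - 1, j] - gap_extend]))
            state = (0, 2, 1)[state]
            i -= 1
        else:
            state = int(np.argmax([M[i, j - 1] - gap_open,
                                   Ix[i, j - 1] - gap_open,
                                   Iy[i, j - 1] - gap_extend]))
            state = (0, 1, 2)[state]
            j -= 1
    pairs.reverse()
    cons_a, cons_b = a.consensus(), b.consensus()
    n_id = sum(cons_a[i] == cons_b[j] for i, j in pairs)
    n_aln = len(pairs)
    return AlignmentResult(
        score=score,
        pairs=pairs,
        percent_identity=100.0 * n_id / n_aln if n_aln else 0.0,
        coverage_a=n_aln / la,
        coverage_b=n_aln / lb,
    )


# ---------------------------------------------------------------------------
# 4-4-1 network over alignment features
# ---------------------------------------------------------------------------


@dataclass
class MlpModel:
    """Logistic-activation 4-4-1 network over alignment features.

    Features: (alignment score, percent identity, coverage of profile 1,
    coverage of profile 2).  Output in (0, 1) is read as the probability
    that the aligned pair shares a GO term, then calibrated downstream.
    """

    w1: np.ndarray  # (4, 4) input -> hidden
    b1: np.ndarray  # (4,)
    w2: np.ndarray  # (4,) hidden -> output
    b2: float
    feature_mean: np.ndarray = field(default_factory=lambda: np.zeros(4))
    feature_scale: np.ndarray = field(default_factory=lambda: np.ones(4))

    def forward(self, features: Sequence[float]) -> float:
        x = (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_scale
        h = 1.0 / (1.0 + np.exp(-(x @ self.w1 + self.b1)))
        z = h @ self.w2 + self.b2
        return float(1.0 / (1.0 + np.exp(-z)))


def per_term_vectors(
    features: Sequence[float], n_shared: int, n_unshared: int
) -> list[tuple[tuple[float, ...], bool]]:
    """Per-GO-term training vectors for one alignment.

    An alignment between proteins sharing m GO terms and mismatching k
    yields m positive and k negative copies of its feature vector, so
    network outputs approximate per-term occurrence probabilities.
    """
    fv = tuple(float(f) for f in features)
    return [(fv, True)] * n_shared + [(fv, False)] * n_unshared


def mlp_train(
    vectors: Sequence[tuple[Sequence[float], bool]],
    seed: int = 0,
    max_iter: int = 500,
) -> MlpModel:
    """Train the 4-4-1 network on labelled alignment feature vectors.

    Gradient-based training of a logistic-activation network on
    cross-entropy; features are standardized internally.  Requires at
    least 50 vectors with both labels present.
    """
    if len(vectors) < 50:
        raise ValueError("need at least 50 training vectors")
    X = np.asarray([v[0] for v in vectors], dtype=float)
    y = np.asarray([bool(v[1]) for v in vectors])
    if X.shape[1] != 4:
        raise ValueError("feature vectors must have 4 components")
    if y.all() or not y.any():
        raise ValueError("training data contains a single class")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    clf = MLPClassifier(
        hidden_layer_sizes=(4,), activation="logistic", solver="lbfgs",
        alpha=1e-4, max_iter=max_iter, random_state=seed,
    )
    clf.fit((X - mean) / scale, y)
    return MlpModel(
        w1=clf.coefs_[0], b1=clf.intercepts_[0],
        w2=clf.coefs_[1].ravel(), b2=float(clf.intercepts_[1][0]),
        feature_mean=mean, feature_scale=scale,
    )


def mlp_score(model: MlpModel, features: Sequence[float]) -> float:
    """Forward pass of the 4-4-1 network; output strictly in (0, 1)."""
    arr = np.asarray(features, dtype=float)
    if arr.shape != (4,) or not np.all(np.isfinite(arr)):
        raise ValueError("features must be a finite 4-vector")
    return model.forward(arr)
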