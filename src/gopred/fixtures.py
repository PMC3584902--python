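"""Deterministic synthetic fixtures for every input format the package reads.

Every generator is a pure function of a :class:`FixtureSpec`: the same
seed reproduces byte-identical files.  The toy world emulates, at desk
scale, a benchmark of well-characterized proteins: a layered GO-like DAG
per namespace, an annotation corpus with a controlled experimental
evidence fraction, flat-text records and sequences carrying term-linked
marker signal, PSSMs, homology hit tables, orthologous groups, and noisy
per-method prediction sets whose correctness statistics follow a known
logistic — so calibration recovery, ensemble behavior and COGIC scoring
can all be checked against ground truth the generator wrote down.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from gopred.calibration import ScoredOutcome
from gopred.corpus import (
    AnnotationCorpus,
    AnnotationRecord,
    EXPERIMENTAL_CODES,
    write_gaf,
)
from gopred.ensemble import Prediction, write_predictions
from gopred.homology import AA_ORDER, HomologyHit, Pssm
from gopred.ontology import GoDag, write_obo

_NS_PREFIX = {"MF": 1, "BP": 2}
_EXPERIMENTAL = sorted(EXPERIMENTAL_CODES)
_NON_EXPERIMENTAL = ["IEA", "ISS"]


@dataclass
class MethodNoise:
    """Noise model for one simulated component predictor."""

    tp_rate: float = 0.8            # chance a true term is emitted
    true_conf_mean: float = 0.7     # Beta mean for correct predictions
    decoy_conf_mean: float = 0.2    # Beta mean for decoys
    conf_concentration: float = 25.0
    decoys_per_target: int = 2


@dataclass
class FixtureSpec:
    """All knobs of the synthetic world; same seed => identical bytes."""

    seed: int = 0
    n_terms: int = 40               # per namespace
    branching: int = 3
    n_proteins: int = 100
    annotations_per_protein: int = 3
    experimental_fraction: float = 0.8
    methods: dict[str, MethodNoise] = field(default_factory=lambda: {
        "method_a": MethodNoise(),
        "method_b": MethodNoise(),
    })
    # generating logistic for calibration-recovery experiments
    cal_a: float = 0.9
    cal_b: float = 5.0
    cal_c: float = 1.2
    cal_score_lo: float = -5.0
    cal_score_hi: float = 10.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng([self.seed, stream])


def _term_id(ns: str, index: int) -> str:
    return f"GO:{_NS_PREFIX[ns]}{index:06d}"


def make_toy_dag(spec: FixtureSpec, path=None) -> GoDag:
    """Layered random DAG per namespace (MF and BP).

    Layer widths grow by the branching factor; each non-root term gets
    1-2 parents drawn from the previous one or two layers, so the graph
    is acyclic by construction and every term reaches its root.
    """
    namespace: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    for ns in ("MF", "BP"):
        rng = spec.rng(10 + _NS_PREFIX[ns])
        root = _term_id(ns, 0)
        namespace[root] = ns
        names[root] = f"{ns} root"
        layers: list[list[str]] = [[root]]
        made = 1
        width = 1
        while made < spec.n_terms:
            width = min(width * spec.branching, spec.n_terms - made)
            layer: list[str] = []
            for _ in range(width):
                term = _term_id(ns, made)
                namespace[term] = ns
                names[term] = f"{ns} term {made}"
                pool = layers[-1] + (layers[-2] if len(layers) > 1 and len(layers[-1]) > 1 else [])
                n_parents = int(rng.integers(1, 3)) if len(pool) > 1 else 1
                parents = [layers[-1][int(rng.integers(len(layers[-1])))]]
                while len(parents) < n_parents:
                    cand = pool[int(rng.integers(len(pool)))]
                    if cand not in parents:
                        parents.append(cand)
                edges.extend((term, p) for p in parents)
                layer.append(term)
                made += 1
            layers.append(layer)
    dag = GoDag(namespace=namespace, is_a_edges=sorted(edges), names=names)
    if path is not None:
        write_obo(dag, path)
    return dag


def make_toy_corpus(
    dag: GoDag, spec: FixtureSpec, path=None
) -> tuple[AnnotationCorpus, dict]:
    """Leaf-biased random annotations with a controlled evidence mix.

    Each protein lives in one namespace and is annotated to distinct
    terms sampled with depth-proportional weights (deeper = likelier).
    Returns the corpus plus bookkeeping: the generator's own
    ancestor-propagated per-term counts (computed by the brute-force
    add-1-to-every-ancestor rule) and its experimental-record tally.
    """
    rng = spec.rng(20)
    records: list[AnnotationRecord] = []
    terms_by_ns = {
        ns: sorted(t for t, n in dag.namespace.items()
                   if n == ns and not dag.is_root(t))
        for ns in ("MF", "BP")
    }
    n_experimental = 0
    for i in range(spec.n_proteins):
        protein = f"P{i:04d}"
        ns = "MF" if i % 2 == 0 else "BP"
        pool = terms_by_ns[ns]
        weights = np.array([dag.depth(t) for t in pool], dtype=float)
        weights /= weights.sum()
        k = min(spec.annotations_per_protein, len(pool))
        chosen = rng.choice(len(pool), size=k, replace=False, p=weights)
        for idx in sorted(chosen):
            if rng.random() < spec.experimental_fraction:
                ev = _EXPERIMENTAL[int(rng.integers(len(_EXPERIMENTAL)))]
                n_experimental += 1
            else:
                ev = _NON_EXPERIMENTAL[int(rng.integers(len(_NON_EXPERIMENTAL)))]
            records.append(AnnotationRecord(protein, pool[idx], ev, ns))
    corpus = AnnotationCorpus(records)
    # brute-force propagated counts: per protein, +1 to every term in the
    # union of its annotations' ancestor closures
    expected_counts: dict[str, int] = {}
    for ns in ("MF", "BP"):
        for protein, terms in corpus.by_protein(ns).items():
            closure: set[str] = set()
            for t in terms:
                closure |= dag.ancestors(t)
            for t in closure:
                expected_counts[t] = expected_counts.get(t, 0) + 1
    if path is not None:
        write_gaf(corpus, path)
    return corpus, {
        "expected_counts": expected_counts,
        "n_experimental": n_experimental,
    }


def make_calibration_outcomes(
    spec: FixtureSpec, n: int = 2000
) -> list[ScoredOutcome]:
    """Benchmark outcomes whose true-positive probability follows the
    spec's generating logistic a / (1 + b exp(-c s)).

    Raw scores are uniform over the spec's score range; the label is
    Bernoulli in the logistic.  Feeding these through binning + fitting
    should recover the generating parameters.
    """
    rng = spec.rng(30)
    scores = rng.uniform(spec.cal_score_lo, spec.cal_score_hi, size=n)
    p = spec.cal_a / (1.0 + spec.cal_b * np.exp(-spec.cal_c * scores))
    labels = rng.random(n) < p
    return [ScoredOutcome(float(s), bool(l)) for s, l in zip(scores, labels)]


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def make_noisy_predictions(
    corpus: AnnotationCorpus,
    dag: GoDag,
    spec: FixtureSpec,
    out_dir=None,
) -> tuple[dict[str, list[Prediction]], dict[str, set[str]]]:
    """Per-method noisy prediction sets with a ground-truth key.

    For each simulated method and protein: every true term is emitted
    with probability ``tp_rate`` at a high-mean Beta confidence; decoy
    terms — sampled outside the ancestor closure of the truth, so
    correctness is unambiguous under expansion — get low-mean
    confidences.  Raw scores are Gaussian around class-conditional
    means.  Returns (method -> predictions, protein -> true term set).
    """
    truth = corpus.by_protein()
    terms_by_ns = {
        ns: sorted(t for t, n in dag.namespace.items()
                   if n == ns and not dag.is_root(t))
        for ns in ("MF", "BP")
    }
    predictions: dict[str, list[Prediction]] = {}
    for m_idx, (tag, noise) in enumerate(sorted(spec.methods.items())):
        rng = spec.rng(40 + m_idx)
        at, bt = _beta_params(noise.true_conf_mean, noise.conf_concentration)
        ad, bd = _beta_params(noise.decoy_conf_mean, noise.conf_concentration)
        preds: list[Prediction] = []
        for protein in sorted(truth):
            true_terms = truth[protein]
            ns = dag.namespace[next(iter(true_terms))]
            closure = dag.expand(true_terms)
            decoy_pool = [t for t in terms_by_ns[ns] if t not in closure]
            for term in sorted(true_terms):
                if rng.random() < noise.tp_rate:
                    conf = float(np.clip(rng.beta(at, bt), 0.0, 1.0))
                    preds.append(Prediction(protein, term, float(rng.normal(2.0, 1.0)),
                                            conf, tag))
            n_decoys = min(noise.decoys_per_target, len(decoy_pool))
            for idx in rng.choice(len(decoy_pool), size=n_decoys, replace=False):
                conf = float(np.clip(rng.beta(ad, bd), 0.0, 1.0))
                preds.append(Prediction(protein, decoy_pool[int(idx)],
                                        float(rng.normal(-2.0, 1.0)), conf, tag))
        predictions[tag] = preds
        if out_dir is not None:
            write_predictions(preds, Path(out_dir) / f"{tag}.tsv")
    return predictions, truth


def make_toy_sequences(
    corpus: AnnotationCorpus,
    dag: GoDag,
    spec: FixtureSpec,
    path=None,
    length: int = 150,
    motif_copies: int = 6,
) -> dict[str, str]:
    """Random protein sequences carrying term-linked trigram motifs.

    Each GO term gets a fixed 3-residue marker motif; a protein's
    sequence has several copies of the motif of each of its annotated
    terms inserted at random positions, so a trigram classifier can
    recover the annotations.
    """
    rng = spec.rng(50)
    aa = np.array(list(AA_ORDER))
    motif_rng = spec.rng(51)
    motifs = {
        t: "".join(motif_rng.choice(aa, size=3))
        for t in sorted(dag.namespace)
    }
    sequences: dict[str, str] = {}
    for protein in sorted(corpus.proteins):
        seq = list(rng.choice(aa, size=length))
        for term in sorted(corpus.terms_for(protein)):
            for _ in range(motif_copies):
                pos = int(rng.integers(0, length - 3))
                seq[pos:pos + 3] = motifs[term]
        sequences[protein] = "".join(seq)
    if path is not None:
        with open(path, "w") as fh:
            for protein, seq in sequences.items():
                fh.write(f">{protein}\n{seq}\n")
    return sequences


def make_toy_records(
    corpus: AnnotationCorpus, dag: GoDag, spec: FixtureSpec, path=None
) -> dict[str, str]:
    """Swiss-Prot-style flat records with term-linked marker words.

    Each annotated term contributes a distinctive word to the protein's
    DE line; KW and FT lines add shared, uninformative filler.
    """
    rng = spec.rng(60)
    records: dict[str, str] = {}
    fillers = ["protein", "putative", "conserved", "domain"]
    for protein in sorted(corpus.proteins):
        words = [f"func{t.split(':')[1]}" for t in sorted(corpus.terms_for(protein))]
        de = "DE   " + " ".join(words + [fillers[int(rng.integers(len(fillers)))]])
        kw = "KW   " + "; ".join(rng.choice(fillers, size=2, replace=False))
        start = int(rng.integers(1, 200))
        end = start + int(rng.integers(10, 120))
        ft = f"FT   DOMAIN {start} {end} Conserved"
        records[protein] = f"ID   {protein}\n{de}\n{kw}\n{ft}\n"
    if path is not None:
        with open(path, "w") as fh:
            for protein in sorted(records):
                fh.write(records[protein] + "//\n")
    return records


def make_toy_pssm(
    spec: FixtureSpec, name: str, length: int, stream: int = 70
) -> Pssm:
    """Random PSSM: Dirichlet target frequencies peaked on a random
    consensus, log-odds = log2(freq / background)."""
    rng = np.random.default_rng([spec.seed, stream, zlib.crc32(name.encode())])
    consensus = rng.integers(0, 20, size=length)
    alpha = np.ones((length, 20))
    alpha[np.arange(length), consensus] = 25.0
    freqs = np.vstack([rng.dirichlet(alpha[i]) for i in range(length)])
    log_odds = np.log2(np.maximum(freqs, 1e-4) / 0.05)
    return Pssm(name=name, log_odds=np.round(log_odds, 2), target_freq=freqs)


def write_pssm(pssm: Pssm, path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (log-odds + percentages)."""
    cons = pssm.consensus()
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER) + "\n")
        for i in range(len(pssm)):
            lo = " ".join(f"{v:6.2f}" for v in pssm.log_odds[i])
            pc = " ".join(f"{100 * v:6.2f}" for v in pssm.target_freq[i])
            fh.write(f"{i + 1} {cons[i]} {lo} {pc} 0.0 0.0\n")


def make_toy_hits(
    corpus: AnnotationCorpus, spec: FixtureSpec, n_targets: int = 10,
    hits_per_target: int = 5, path=None,
) -> list[HomologyHit]:
    """Random tabular homology hits with varied coverage, identity and
    bit score.

    Half the targets are annotated corpus proteins (so hit-transfer can
    be benchmarked and self-calibrated against their own annotations),
    half are novel ``T####`` ids; subjects are always corpus proteins.
    """
    rng = spec.rng(80)
    subjects = sorted(corpus.proteins)
    hits: list[HomologyHit] = []
    rows = []
    for i in range(n_targets):
        target = subjects[i % len(subjects)] if i < n_targets // 2 else f"T{i:04d}"
        qlen = int(rng.integers(100, 300))
        for _ in range(hits_per_target):
            subject = subjects[int(rng.integers(len(subjects)))]
            if subject == target:
                continue
            slen = int(rng.integers(100, 300))
            cov = float(rng.uniform(0.6, 1.0))
            qstart = 1
            qend = max(1, int(round(cov * qlen)))
            ident = float(rng.uniform(20, 95))
            bit = float(np.round(rng.uniform(30, 400), 1))
            hits.append(HomologyHit(target, subject, bit, ident,
                                    (qend - qstart + 1) / qlen, (qend - qstart + 1) / slen))
            rows.append((target, subject, ident, qend - qstart + 1, qstart, qend,
                         qstart, qend, 1e-5, bit, qlen, slen))
    if path is not None:
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
    return hits


def make_toy_groups(
    corpus: AnnotationCorpus, spec: FixtureSpec, n_groups: int = 20, path=None
) -> dict[str, str]:
    """Random partition of the corpus proteins into orthologous groups."""
    rng = spec.rng(90)
    proteins = sorted(corpus.proteins)
    assignment = {
        p: f"NOG{int(rng.integers(n_groups)):04d}" for p in proteins
    }
    if path is not None:
        with open(path, "w") as fh:
            for p in proteins:
                fh.write(f"{p}\t{assignment[p]}\n")
    return assignment


def make_workspace(directory, spec: FixtureSpec | None = None) -> dict:
    """Materialize a complete toy workspace under *directory*.

    Writes the OBO ontology, GAF annotations, flat records, FASTA
    sequences, hit table, group file, per-method prediction files, the
    ground-truth key and the spec itself; returns the path map.
    """
    spec = spec or FixtureSpec()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": directory / "toy.obo",
        "gaf": directory / "annotations.gaf",
        "records": directory / "records.txt",
        "fasta": directory / "sequences.fasta",
        "hits": directory / "hits.tsv",
        "groups": directory / "groups.tsv",
        "pssm_dir": directory / "pssm",
        "predictions": directory / "predictions",
        "truth": directory / "truth.json",
        "spec": directory / "fixture_spec.json",
    }
    paths["predictions"].mkdir(exist_ok=True)
    paths["pssm_dir"].mkdir(exist_ok=True)
    dag = make_toy_dag(spec, paths["obo"])
    corpus, _ = make_toy_corpus(dag, spec, paths["gaf"])
    make_toy_records(corpus, dag, spec, paths["records"])
    make_toy_sequences(corpus, dag, spec, paths["fasta"])
    make_toy_hits(corpus, spec, path=paths["hits"])
    make_toy_groups(corpus, spec, path=paths["groups"])
    for name in sorted(corpus.proteins)[:8] + ["T0000", "T0001"]:
        write_pssm(make_toy_pssm(spec, name, length=30),
                   paths["pssm_dir"] / f"{name}.pssm")
    _, truth = make_noisy_predictions(corpus, dag, spec, out_dir=paths["predictions"])
    with open(paths["truth"], "w") as fh:
        json.dump({p: sorted(ts) for p, ts in truth.items()}, fh, indent=0, sort_keys=True)
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(spec), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
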