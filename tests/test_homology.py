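"""Hit transfer, ortholog voting, profile alignment and the 4-4-1 network."""

import numpy as np
import pytest

from _oracles import bf_group_by_max, exhaustive_best_score
from gopred.calibration import CalibrationModel, estimate_precision
from gopred.corpus import AnnotationCorpus, AnnotationRecord
from gopred.fixtures import FixtureSpec, make_toy_pssm, write_pssm
from gopred.homology import (
    HomologyHit,
    MlpModel,
    Pssm,
    align_profiles,
    mlp_score,
    mlp_train,
    ortho_transfer,
    per_term_vectors,
    profile_column_score,
    read_hits_table,
    read_pssm,
    transfer_from_hits,
)

MODEL = CalibrationModel(a=0.95, b=2.0, c=0.02, method_tag="homology")


def _hit(target="T1", subject="S1", bit=50.0, ident=40.0, cov=0.9):
    return HomologyHit(target, subject, bit, ident, cov, cov)


def _annotations(mapping):
    return AnnotationCorpus([
        AnnotationRecord(p, t, "IDA", "MF")
        for p, terms in mapping.items() for t in terms
    ])


class TestTransferFromHits:
    def test_coverage_below_cutoff_discarded(self):
        ann = _annotations({"S1": {"GO:1"}})
        assert transfer_from_hits([_hit(cov=0.84)], ann, MODEL) == []
        assert len(transfer_from_hits([_hit(cov=0.85)], ann, MODEL)) == 1

    def test_max_bit_score_rule(self):
        ann = _annotations({"S1": {"GO:1"}, "S2": {"GO:1"}})
        preds = transfer_from_hits(
            [_hit(subject="S1", bit=50.0), _hit(subject="S2", bit=80.0)],
            ann, MODEL)
        assert len(preds) == 1
        assert preds[0].raw_score == 80.0
        assert preds[0].precision == estimate_precision(MODEL, 80.0)

    def test_matches_group_by_max_oracle(self):
        rng = np.random.default_rng(12)
        subjects = {f"S{i}": {f"GO:{t}" for t in rng.integers(0, 10, size=3)}
                    for i in range(6)}
        ann = _annotations(subjects)
        hits = [
            _hit(target=f"T{int(rng.integers(3))}",
                 subject=f"S{int(rng.integers(6))}",
                 bit=float(np.round(rng.uniform(20, 300), 1)))
            for _ in range(30)
        ]
        preds = transfer_from_hits(hits, ann, MODEL)
        rows = [
            (h.target, term, h.bit_score)
            for h in hits for term in subjects[h.subject]
        ]
        expected = bf_group_by_max(rows)
        assert {(p.target, p.term): p.raw_score for p in preds} == expected

    def test_precision_monotone_in_bit_score(self):
        ann = _annotations({"S1": {"GO:1"}, "S2": {"GO:2"}})
        p_low = transfer_from_hits([_hit(bit=10.0)], ann, MODEL)[0].precision
        p_high = transfer_from_hits([_hit(bit=200.0)], ann, MODEL)[0].precision
        assert p_high >= p_low


class TestOrthoTransfer:
    def test_shared_fractions(self, chain_dag):
        ann = _annotations({
            "A": {"GO:1000002"}, "B": {"GO:1000002"},
            "C": {"GO:1000002"}, "D": {"GO:1000001"},
        })
        groups = {p: "g1" for p in "ABCDT"}
        preds = {p.term: p.precision
                 for p in ortho_transfer(groups, ann, chain_dag, targets=["T"])}
        # leaf on 3 of 4 annotated members; mid and root on all 4 (expansion)
        assert preds["GO:1000002"] == pytest.approx(0.75)
        assert preds["GO:1000001"] == pytest.approx(1.0)

    def test_target_excluded_from_tally(self, chain_dag):
        ann = _annotations({"A": {"GO:1000002"}, "T": {"GO:1000001"}})
        preds = ortho_transfer({"A": "g", "T": "g"}, ann, chain_dag, targets=["T"])
        assert {p.term: p.precision for p in preds}["GO:1000002"] == 1.0

    def test_group_without_annotated_members_empty(self, chain_dag):
        ann = _annotations({})
        assert ortho_transfer({"T": "g"}, ann, chain_dag, targets=["T"]) == []

    def test_matches_nested_loop_oracle(self, toy_dag, toy_corpus):
        corpus, _ = toy_corpus
        rng = np.random.default_rng(5)
        proteins = sorted(corpus.proteins)
        groups = {p: f"g{int(rng.integers(20))}" for p in proteins}
        preds = ortho_transfer(groups, corpus, toy_dag)
        expanded = {p: toy_dag.expand(ts) for p, ts in corpus.by_protein().items()}
        got = {(p.target, p.term): p.precision for p in preds}
        for (target, term), prec in got.items():
            voters = [q for q in proteins
                      if groups[q] == groups[target] and q != target and q in expanded]
            n_with = sum(term in expanded[q] for q in voters)
            assert prec == pytest.approx(n_with / len(voters))
            assert 0.0 < prec <= 1.0
            if prec == 1.0:
                assert n_with == len(voters)


class TestProfileColumnScore:
    def test_uniform_closed_form(self):
        tf = np.full(20, 1 / 20)
        lo = np.ones(20)
        assert profile_column_score((lo, tf), (lo, tf)) == pytest.approx(2.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = (rng.normal(size=20), rng.dirichlet(np.ones(20)))
            y = (rng.normal(size=20), rng.dirichlet(np.ones(20)))
            assert profile_column_score(x, y) == pytest.approx(
                profile_column_score(y, x), abs=1e-12)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        x_lo, y_lo = rng.normal(size=20), rng.normal(size=20)
        x_tf, y_tf = rng.dirichlet(np.ones(20)), rng.dirichlet(np.ones(20))
        expected = float(np.dot(x_tf, y_lo) / x_tf.sum()
                         + np.dot(y_tf, x_lo) / y_tf.sum())
        assert profile_column_score((x_lo, x_tf), (y_lo, y_tf)) == pytest.approx(
            expected, abs=1e-12)


class TestAlignProfiles:
    def test_self_alignment(self):
        p = make_toy_pssm(FixtureSpec(seed=6), "A", 10)
        aln = align_profiles(p, p)
        assert aln.coverage_a == aln.coverage_b == 1.0
        assert aln.percent_identity == 100.0
        assert len(aln.pairs) == 10

    def test_swap_symmetric_score(self):
        spec = FixtureSpec(seed=7)
        a = make_toy_pssm(spec, "A", 8)
        b = make_toy_pssm(spec, "B", 11)
        assert align_profiles(a, b).score == pytest.approx(
            align_profiles(b, a).score, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        la, lb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        a = make_toy_pssm(FixtureSpec(seed=seed), "a", la)
        b = make_toy_pssm(FixtureSpec(seed=seed + 100), "b", lb)
        from gopred.homology import _column_score_matrix
        S = _column_score_matrix(a, b)
        expected = exhaustive_best_score(S.tolist(), 11.0, 1.0)
        assert align_profiles(a, b).score == pytest.approx(expected, abs=1e-9)

    def test_score_at_least_gapless_diagonal(self):
        spec = FixtureSpec(seed=8)
        a = make_toy_pssm(spec, "A", 9)
        b = make_toy_pssm(spec, "B", 9)
        from gopred.homology import _column_score_matrix
        diag = float(np.trace(_column_score_matrix(a, b)))
        assert align_profiles(a, b).score >= diag - 1e-9


def test_pssm_ascii_roundtrip(tmp_path):
    p = make_toy_pssm(FixtureSpec(seed=9), "P", 14)
    path = tmp_path / "p.pssm"
    write_pssm(p, path)
    p2 = read_pssm(path)
    assert len(p2) == 14
    np.testing.assert_allclose(p2.target_freq, p.target_freq, atol=1e-4)
    np.testing.assert_allclose(p2.target_freq.sum(axis=1), 1.0, atol=1e-6)


def test_pssm_simplex_invariant_enforced():
    with pytest.raises(ValueError):
        Pssm(name="bad", log_odds=np.zeros((3, 20)),
             target_freq=np.full((3, 20), 0.1))


def test_hits_table_reader(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("T1\tS1\t45.0\t90\t1\t90\t5\t94\t1e-20\t180.5\t100\t120\n")
    (hit,) = read_hits_table(path)
    assert hit.bit_score == 180.5
    assert hit.target_coverage == pytest.approx(0.9)
    assert hit.subject_coverage == pytest.approx(90 / 120)


class TestMlp:
    def test_per_term_vector_counts(self):
        vectors = per_term_vectors((1.0, 2.0, 3.0, 4.0), 5, 3)
        assert len(vectors) == 8
        assert sum(label for _, label in vectors) == 5

    def test_separable_accuracy(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(200, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 1.5]) > 0
        model = mlp_train(list(zip(X.tolist(), y.tolist())), seed=0)
        acc = np.mean([(mlp_score(model, x) > 0.5) == t
                       for x, t in zip(X.tolist(), y.tolist())])
        assert acc >= 0.98

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(400, 4))
        y = rng.permutation(np.repeat([True, False], 200))
        model = mlp_train(list(zip(X[:200].tolist(), y[:200].tolist())),
                          seed=0, max_iter=200)
        held = np.mean([(mlp_score(model, x) > 0.5) == t
                        for x, t in zip(X[200:].tolist(), y[200:].tolist())])
        assert abs(held - 0.5) < 0.11

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mlp_train([((0.0, 0.0, 0.0, 0.0), True)] * 60)

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            mlp_train([((0.0,) * 4, True), ((1.0,) * 4, False)] * 10)

    def test_zero_weights_output_half(self):
        model = MlpModel(w1=np.zeros((4, 4)), b1=np.zeros(4),
                         w2=np.zeros(4), b2=0.0)
        for x in ([0, 0, 0, 0], [5, -3, 2, 7]):
            assert mlp_score(model, x) == pytest.approx(0.5)

    def test_hand_computed_forward_pass(self):
        w1 = np.array([[0.5, -0.2, 0.1, 0.0],
                       [0.3, 0.4, -0.1, 0.2],
                       [-0.6, 0.1, 0.2, 0.3],
                       [0.0, 0.2, -0.3, 0.1]])
        b1 = np.array([0.1, -0.1, 0.0, 0.2])
        w2 = np.array([0.7, -0.4, 0.5, 0.3])
        model = MlpModel(w1=w1, b1=b1, w2=w2, b2=-0.2)
        x = np.array([1.0, -0.5, 2.0, 0.3])
        h = 1 / (1 + np.exp(-(x @ w1 + b1)))
        expected = float(1 / (1 + np.exp(-(h @ w2 - 0.2))))
        assert mlp_score(model, x) == pytest.approx(expected, abs=1e-12)

    def test_output_bounded(self):
        rng = np.random.default_rng(13)
        model = MlpModel(w1=rng.normal(size=(4, 4)), b1=rng.normal(size=4),
                         w2=rng.normal(size=4), b2=0.5)
        for _ in range(1000):
            out = mlp_score(model, rng.normal(size=4) * 10)
            assert 0.0 < out < 1.0

    def test_nonfinite_features_rejected(self):
        model = MlpModel(w1=np.zeros((4, 4)), b1=np.zeros(4),
                         w2=np.zeros(4), b2=0.0)
        with pytest.raises(ValueError):
            mlp_score(model, [1.0, float("nan"), 0.0, 0.0])
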