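"""Attenuated combination, upward propagation and incompatibility filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bf_filter, bf_propagate
from gopred.corpus import cooccurrence_pairs
from gopred.ensemble import (
    CombinedSet,
    Prediction,
    combine,
    filter_incompatible,
    integrate_target,
    propagate_up,
    read_predictions,
    write_predictions,
)
from gopred.fixtures import FixtureSpec, make_noisy_predictions, make_toy_corpus


def _pred(term, precision, method="m", target="T"):
    return Prediction(target, term, precision, precision, method)


class TestCombine:
    def test_single_unanimous_vote_attenuated(self):
        combined = combine([_pred("GO:1", 1.0)], alpha=0.9)
        assert combined.precisions["GO:1"] == pytest.approx(0.9)

    def test_two_methods_arithmetic(self):
        combined = combine(
            [_pred("GO:1", 0.5, "a"), _pred("GO:1", 0.5, "b")], alpha=0.9)
        assert combined.precisions["GO:1"] == pytest.approx(1 - 0.55 ** 2)
        assert combined.provenance["GO:1"] == {"a", "b"}

    def test_alpha_zero_annihilates(self):
        combined = combine([_pred("GO:1", 0.9), _pred("GO:2", 1.0)], alpha=0.0)
        assert all(v == 0.0 for v in combined.precisions.values())

    @pytest.mark.parametrize("alpha", [-0.1, 1.5])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            combine([_pred("GO:1", 0.5)], alpha=alpha)

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError):
            combine([_pred("GO:1", 0.5, target="A"), _pred("GO:1", 0.5, target="B")])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6),
           st.floats(0, 0.999))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_permutation_invariant_monotone_and_below_one(self, precs, alpha):
        """Combination is order-free, monotone in alpha, and strictly
        below 1 whenever alpha < 1."""
        preds = [_pred("GO:1", p, method=f"m{i}") for i, p in enumerate(precs)]
        forward = combine(preds, alpha=alpha).precisions["GO:1"]
        backward = combine(preds[::-1], alpha=alpha).precisions["GO:1"]
        assert forward == pytest.approx(backward, abs=1e-12)
        assert forward < 1.0
        higher = combine(preds, alpha=min(1.0, alpha + 0.001)).precisions["GO:1"]
        assert higher >= forward - 1e-12


class TestPropagateUp:
    def test_chain_example(self, chain_dag):
        combined = CombinedSet("T", {"GO:1000002": 0.5, "GO:1000001": 0.5})
        out = propagate_up(chain_dag, combined)
        assert out.precisions["GO:1000001"] == pytest.approx(0.75)
        assert out.precisions["GO:1000002"] == pytest.approx(0.5)

    def test_single_term_unchanged(self, chain_dag):
        combined = CombinedSet("T", {"GO:1000002": 0.4})
        assert propagate_up(chain_dag, combined).precisions == {"GO:1000002": 0.4}

    def test_snapshot_oracle_and_monotonicity(self, toy_dag):
        """Random 30-term sets match the nested-loop snapshot oracle and
        end ancestor-monotone within the predicted set."""
        terms = sorted(toy_dag.terms)
        rng = np.random.default_rng(21)
        for _ in range(10):
            chosen = rng.choice(terms, size=30, replace=False)
            precs = {t: float(rng.uniform(0.05, 0.95)) for t in chosen}
            out = propagate_up(toy_dag, CombinedSet("T", dict(precs)))
            expected = bf_propagate(precs, toy_dag.depth_difference)
            for t in precs:
                assert out.precisions[t] == pytest.approx(expected[t], abs=1e-12)
            for a in precs:
                for d in precs:
                    diff = toy_dag.depth_difference(a, d)
                    if diff is not None and diff < 0:  # a shallower than d
                        assert out.precisions[a] >= out.precisions[d] - 1e-12


class TestFilterIncompatible:
    def test_lower_precision_dropped(self, chain_dag):
        combined = CombinedSet("T", {"GO:1000001": 0.8, "GO:1000002": 0.3})
        ranked = filter_incompatible(combined, set(), chain_dag)
        assert ranked == [("GO:1000001", 0.8)]

    def test_equal_precision_both_kept(self, chain_dag):
        combined = CombinedSet("T", {"GO:1000001": 0.6, "GO:1000002": 0.6})
        ranked = filter_incompatible(combined, set(), chain_dag)
        assert {t for t, _ in ranked} == {"GO:1000001", "GO:1000002"}

    def test_cooccurring_pair_spared(self, chain_dag):
        combined = CombinedSet("T", {"GO:1000001": 0.8, "GO:1000002": 0.3})
        cooccur = {("GO:1000001", "GO:1000002")}
        assert len(filter_incompatible(combined, cooccur, chain_dag)) == 2

    def test_matches_single_pass_oracle(self, toy_dag, toy_corpus):
        corpus, _ = toy_corpus
        cooccur = cooccurrence_pairs(corpus, toy_dag)
        rng = np.random.default_rng(22)
        terms = sorted(t for t in toy_dag.terms if toy_dag.namespace[t] == "MF")
        for _ in range(10):
            chosen = rng.choice(terms, size=15, replace=False)
            precs = {t: float(rng.uniform(0, 1)) for t in chosen}
            ranked = filter_incompatible(
                CombinedSet("T", dict(precs)), cooccur, toy_dag)
            survivors = {t for t, _ in ranked}
            assert survivors == bf_filter(precs, cooccur, toy_dag.depth_difference)
            ordered = [p for _, p in ranked]
            assert ordered == sorted(ordered, reverse=True)

    def test_never_removes_unpartnered_term(self, diamond_dag):
        """A term with no ancestor-related non-co-occurring partner
        always survives."""
        a, e = "GO:1000001", "GO:1000005"  # e below a; b unrelated branch
        b = "GO:1000002"
        combined = CombinedSet("T", {a: 0.9, e: 0.1, b: 0.05})
        ranked = filter_incompatible(combined, set(), diamond_dag)
        survivors = {t for t, _ in ranked}
        assert b in survivors      # no defined depth difference with a or e
        assert e not in survivors  # ancestor-related to a, lower precision


def test_integrate_pipeline_smoke(toy_dag):
    spec = FixtureSpec(seed=23, n_proteins=10)
    corpus, _ = make_toy_corpus(toy_dag, spec)
    cooccur = cooccurrence_pairs(corpus, toy_dag)
    methods, truth = make_noisy_predictions(corpus, toy_dag, spec)
    target = sorted(truth)[0]
    preds = [p for preds in methods.values() for p in preds if p.target == target]
    ranked = integrate_target(preds, toy_dag, cooccur)
    assert ranked
    assert all(0 < p < 1 for _, p in ranked)


def test_prediction_file_roundtrip(tmp_path):
    preds = [Prediction("T1", "GO:0000001", 0.5, 0.87, "m"),
             Prediction("T2", "GO:0000002", 0.1, 0.25, "m")]
    path = tmp_path / "preds.tsv"
    write_predictions(preds, path)
    # reader tolerates CAFA header/footer lines
    content = "AUTHOR team\nMODEL 1\n" + path.read_text() + "END\n"
    path.write_text(content)
    reread = read_predictions(path, method="m")
    assert [(p.target, p.term, p.precision) for p in reread] == [
        ("T1", "GO:0000001", 0.87), ("T2", "GO:0000002", 0.25)]
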