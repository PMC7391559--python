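"""Per-bin ancestral reconstruction: ML pruning, Sankoff parsimony,
state calling, smoothing and tip/ancestor comparison."""

import warnings

import numpy as np
import pytest

import nichebar as nb
from nichebar.ancestral import (
    DEFAULT_TIE_TOL,
    STATES,
    call_state_ml,
    call_state_parsimony,
    ml_asr_bin,
    parsimony_asr_bin,
)
from nichebar.binning import SUITABLE, UNKNOWN, UNSUITABLE
from nichebar.phylo import parse_newick

from _oracles import enumerate_likelihood, enumerate_parsimony
from conftest import random_tree


def random_states(rng, tree):
    return {l: STATES[rng.integers(3)] for l in tree.tip_labels}


class TestMLvsEnumeration:
    def test_pruning_matches_enumeration(self, rng):
        """Pruning likelihood and marginals equal exhaustive enumeration."""
        checked = 0
        while checked < 25:
            tree = random_tree(rng, int(rng.integers(3, 7)))
            ts = random_states(rng, tree)
            if len(set(ts.values())) == 1:
                continue
            res = ml_asr_bin(tree, ts)
            ll, post = enumerate_likelihood(tree, ts, res.q)
            assert res.log_likelihood == pytest.approx(ll, abs=1e-9)
            for nid, p in post.items():
                np.testing.assert_allclose(res.marginals[nid].probs, p, atol=1e-9)
            checked += 1

    def test_identical_tips_pull_root_towards_their_state(self):
        tree = parse_newick("(A:0.01,B:0.01);")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ml_asr_bin(tree, {"A": "1", "B": "1"})
        root = tree.labels[tree.root]
        assert res.marginals[root].probs[1] > 0.99

    def test_monomorphic_tips_warn_and_pin_rate(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = ml_asr_bin(tree, {"A": "0", "B": "0", "C": "0"})
        assert res.q == pytest.approx(1e-8)
        for m in res.marginals.values():
            assert m.probs.sum() == pytest.approx(1.0)

    def test_branch_length_scaling_invariance(self, rng):
        """Multiplying branch lengths by c and dividing q by c preserves logLik."""
        tree = random_tree(rng, 6)
        ts = {l: STATES[i % 3] for i, l in enumerate(tree.tip_labels)}
        res = ml_asr_bin(tree, ts)
        scaled = nb.Phylogeny(
            children=[list(c) for c in tree.children],
            lengths=[3.0 * b for b in tree.lengths],
            labels=list(tree.labels),
        )
        from nichebar.ancestral import _log_likelihood, _tip_partials

        tipL = _tip_partials(scaled, ts)
        assert _log_likelihood(scaled, tipL, res.q / 3.0) == pytest.approx(
            res.log_likelihood, abs=1e-9
        )

    def test_label_permutation_equivariance(self, rng):
        """Relabeling states consistently permutes marginals (ER symmetry)."""
        perm = {"0": "1", "1": "?", "?": "0"}
        tree = random_tree(rng, 5)
        ts = random_states(rng, tree)
        if len(set(ts.values())) == 1:
            ts[tree.tip_labels[0]] = perm[ts[tree.tip_labels[0]]]
        res = ml_asr_bin(tree, ts)
        res_p = ml_asr_bin(tree, {k: perm[v] for k, v in ts.items()})
        idx = [STATES.index(perm[s]) for s in STATES]
        for nid in res.marginals:
            np.testing.assert_allclose(
                res_p.marginals[nid].probs[idx], res.marginals[nid].probs, atol=1e-6
            )

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            nb.Phylogeny(children=[[], [], [0, 1]], lengths=[1.0, -0.5, 0.0],
                         labels=["A", "B", "n2"])


class TestParsimonyVsEnumeration:
    def test_sankoff_matches_enumeration(self, rng):
        """Sankoff cost and MPR state sets equal the exhaustive minimum."""
        for _ in range(30):
            tree = random_tree(rng, int(rng.integers(3, 7)))
            ts = random_states(rng, tree)
            res = parsimony_asr_bin(tree, ts)
            cost, sets = enumerate_parsimony(tree, ts)
            assert res.cost == cost
            for nid, s in sets.items():
                assert res.state_sets[nid] == s

    def test_two_clades_cost_one_ambiguous_root(self, balanced_quartet):
        res = parsimony_asr_bin(
            balanced_quartet, {"A": "1", "B": "1", "C": "0", "D": "0"}
        )
        assert res.cost == 1
        root = balanced_quartet.labels[balanced_quartet.root]
        assert res.state_sets[root] == frozenset({"0", "1"})

    def test_uniform_tips_zero_cost(self, balanced_quartet):
        res = parsimony_asr_bin(balanced_quartet, dict.fromkeys("ABCD", "1"))
        assert res.cost == 0
        assert all(s == frozenset({"1"}) for s in res.state_sets.values())


class TestStateCalls:
    @pytest.mark.parametrize(
        "probs,expected",
        [((0.1, 0.85, 0.05), "1"), ((0.45, 0.45, 0.10), "?"), ((0.9, 0.05, 0.05), "0")],
    )
    def test_ml_calls(self, probs, expected):
        assert call_state_ml(np.array(probs), tie_tol=0.05) == expected

    @pytest.mark.parametrize(
        "state_set,expected",
        [({"1"}, "1"), ({"0", "1"}, "?"), ({"0", "?"}, "?"), ({"0", "1", "?"}, "?")],
    )
    def test_parsimony_calls(self, state_set, expected):
        assert call_state_parsimony(frozenset(state_set)) == expected


class TestSmoothing:
    def make(self, pattern):
        s = nb.build_bin_scheme(nb.EnvRange(0, len(pattern)), 1.0)
        return nb.CharacterVector("n", s, tuple(pattern))

    @pytest.mark.parametrize(
        "before,after",
        [("1011", "1111"), ("0110", "0110"), ("1?0?1", "11111"), ("0?1?0", "0?1?0")],
    )
    def test_span_fill(self, before, after):
        assert "".join(nb.smooth_reconstruction(self.make(before)).states) == after

    def test_no_suitable_bin_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="no suitable bin"):
            out = nb.smooth_reconstruction(self.make("0?0"))
        assert "".join(out.states) == "0?0"

    def test_idempotent_and_monotone(self, rng):
        for _ in range(100):
            pattern = "".join(rng.choice(list("01?"), size=8))
            v = self.make(pattern)
            if v.suitable_span() is None:
                continue
            once = nb.smooth_reconstruction(v)
            assert nb.smooth_reconstruction(once).states == once.states
            assert all(
                a == SUITABLE for a, b in zip(once.states, v.states) if b == SUITABLE
            )


class TestReconstructMatrix:
    def small_matrix(self, states_by_species, width=1.0):
        n = len(next(iter(states_by_species.values())))
        scheme = nb.build_bin_scheme(nb.EnvRange(0, n * width), width)
        rows = [
            nb.CharacterVector(sp, scheme, tuple(states))
            for sp, states in states_by_species.items()
        ]
        return nb.CharacterMatrix(scheme=scheme, rows=rows)

    def test_single_uniform_bin(self, balanced_quartet):
        m = self.small_matrix({sp: "1" for sp in "ABCD"})
        res = nb.reconstruct_matrix(balanced_quartet, m, "ml")
        assert all(v.states == ("1",) for v in res.smoothed.values())

    def test_bin_order_independence(self, balanced_quartet):
        states = {"A": "10?1", "B": "1011", "C": "0?10", "D": "0110"}
        m = self.small_matrix(states)
        rev = self.small_matrix({sp: s[::-1] for sp, s in states.items()})
        res = nb.reconstruct_matrix(balanced_quartet, m, "ml")
        res_rev = nb.reconstruct_matrix(balanced_quartet, rev, "ml")
        for nid in res.raw:
            assert res.raw[nid].states == res_rev.raw[nid].states[::-1]

    def test_tip_species_mismatch_lists_difference(self, balanced_quartet):
        m = self.small_matrix({"A": "1", "B": "1", "C": "1", "E": "1"})
        with pytest.raises(ValueError, match="'D'.*'E'"):
            nb.reconstruct_matrix(balanced_quartet, m, "ml")

    def test_parsimony_and_ml_agree_on_clean_signal(self, balanced_quartet):
        m = self.small_matrix({"A": "110", "B": "110", "C": "011", "D": "011"})
        ml = nb.reconstruct_matrix(balanced_quartet, m, "ml")
        ps = nb.reconstruct_matrix(balanced_quartet, m, "parsimony")
        a = balanced_quartet.labels[balanced_quartet.mrca(["A", "B"])]
        assert ml.smoothed[a].states == ps.smoothed[a].states == tuple("110")

    def test_marginals_normalized(self, balanced_quartet):
        m = self.small_matrix({"A": "1?", "B": "10", "C": "0?", "D": "01"})
        res = nb.reconstruct_matrix(balanced_quartet, m, "ml")
        for arr in res.marginals.values():
            np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-9)


class TestCompare:
    def test_reduction_branch(self):
        labels, summary = nb.compare_tip_to_ancestor(tuple("0110"), tuple("1110"))
        assert labels == [
            "lost", "retained-suitable", "retained-suitable", "retained-unsuitable"
        ]
        assert summary == "reduction"

    def test_identical_vectors_stable(self):
        labels, summary = nb.compare_tip_to_ancestor(tuple("0110"), tuple("0110"))
        assert summary == "stable" and "lost" not in labels and "gained" not in labels

    def test_all_unknown_tip_indeterminate(self):
        labels, summary = nb.compare_tip_to_ancestor(tuple("??"), tuple("10"))
        assert labels == ["indeterminate", "indeterminate"] and summary == "stable"

    def test_mixed_and_expansion(self):
        assert nb.compare_tip_to_ancestor(tuple("11"), tuple("01"))[1] == "expansion"
        assert nb.compare_tip_to_ancestor(tuple("10"), tuple("01"))[1] == "mixed"

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            nb.compare_tip_to_ancestor(tuple("10"), tuple("100"))
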