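"""Independent brute-force oracles used by the test suite.

These enumerate over all internal-state assignments, so they are only
usable on tiny trees, but they depend on nothing from the implementations
they check beyond the shared transition-probability formula.
"""

from __future__ import annotations

import itertools

import numpy as np

from nichebar.ancestral import STATES, er_transition_matrix
from nichebar.phylo import Phylogeny

_SIDX = {s: i for i, s in enumerate(STATES)}


def enumerate_likelihood(tree: Phylogeny, tip_states: dict[str, str], q: float):
    """Exhaustive ER-model likelihood and internal-node posteriors."""
    internal = tree.internal_indices
    P = {
        v: er_transition_matrix(q, tree.lengths[v])
        for v in range(tree.n_nodes)
        if v != tree.root
    }
    total = 0.0
    marg = {v: np.zeros(len(STATES)) for v in internal}
    for assign in itertools.product(range(len(STATES)), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for v in tree.tip_indices:
            st[v] = _SIDX[tip_states[tree.labels[v]]]
        p = 1.0 / len(STATES)  # uniform root prior
        for v in range(tree.n_nodes):
            if v != tree.root:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
        for v in internal:
            marg[v][st[v]] += p
    posteriors = {tree.labels[v]: marg[v] / total for v in internal}
    return float(np.log(total)), posteriors


def enumerate_parsimony(tree: Phylogeny, tip_states: dict[str, str]):
    """Exhaustive minimum unit-cost change count and per-node MPR state sets."""
    internal = tree.internal_indices
    best = None
    sets: dict[int, set[str]] = {v: set() for v in internal}
    for assign in itertools.product(range(len(STATES)), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for v in tree.tip_indices:
            st[v] = _SIDX[tip_states[tree.labels[v]]]
        c = sum(
            st[tree.parent[v]] != st[v] for v in range(tree.n_nodes) if v != tree.root
        )
        if best is None or c < best:
            best = c
            sets = {v: set() for v in internal}
        if c == best:
            for v in internal:
                sets[v].add(STATES[st[v]])
    return best, {tree.labels[v]: frozenset(s) for v, s in sets.items()}
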