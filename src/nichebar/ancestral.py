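"""Binned ancestral range (BAR) reconstruction.

Each bin of a character matrix is treated as an independent discrete
character over the three states ``0`` (unsuitable), ``1`` (suitable) and
``?`` (unknown) and reconstructed on the tree either by maximum likelihood
under an equal-rates (ER/Mk3) Markov model with the pruning algorithm, or
by Sankoff parsimony with unit costs.  The "unknown" symbol is a bona fide
third state, not missing data: ignorance at the tips is itself inherited
evidence and is propagated to ancestors.  Per-node bin vectors are then
smoothed so the reconstructed suitable range is a single contiguous run
(unimodal-response assumption), and tip/ancestor vectors can be compared
bin-by-bin to classify branches as niche expansion, reduction, etc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .binning import (
    SUITABLE,
    UNKNOWN,
    UNSUITABLE,
    BinScheme,
    CharacterMatrix,
    CharacterVector,
)
from .phylo import Phylogeny

#: Fixed state order used for all probability vectors and cost vectors.
STATES = (UNSUITABLE, SUITABLE, UNKNOWN)
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_K = len(STATES)

Q_BOUNDS = (1e-8, 1e3)


def er_transition_matrix(q: float, t: float) -> np.ndarray:
    """P(t) for the 3-state equal-rates model (off-diagonal rate ``q``)."""
    e = np.exp(-_K * q * t)
    p_same = (1.0 + (_K - 1) * e) / _K
    p_diff = (1.0 - e) / _K
    P = np.full((_K, _K), p_diff)
    np.fill_diagonal(P, p_same)
    return P


@dataclass(frozen=True)
class NodeMarginals:
    node_id: str
    probs: np.ndarray  # order STATES, sums to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (_K,) or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("marginals must be 3 non-negative values summing to 1")
        object.__setattr__(self, "probs", p)


@dataclass
class BinMLResult:
    """ML reconstruction of a single bin: fitted rate, marginals, logLik."""

    q: float
    marginals: dict[str, NodeMarginals]
    log_likelihood: float


@dataclass
class BinParsimonyResult:
    """Sankoff reconstruction of a single bin."""

    cost: float
    state_sets: dict[str, frozenset[str]]


def _tip_partials(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    unknown_as_ambiguous: bool = False,
) -> np.ndarray:
    missing = set(tree.tip_labels) - set(tip_states)
    if missing:
        raise ValueError(f"tips without a state: {sorted(missing)}")
    L = np.zeros((tree.n_nodes, _K))
    for v in tree.tip_indices:
        s = tip_states[tree.labels[v]]
        if s not in _STATE_INDEX:
            raise ValueError(f"invalid tip state {s!r} for {tree.labels[v]}")
        if unknown_as_ambiguous and s == UNKNOWN:
            # comparison mode: "?" read as {0, 1} rather than a third state
            L[v, _STATE_INDEX[UNSUITABLE]] = 1.0
            L[v, _STATE_INDEX[SUITABLE]] = 1.0
        else:
            L[v, _STATE_INDEX[s]] = 1.0
    return L


def _prune(tree: Phylogeny, tipL: np.ndarray, q: float):
    """Post-order partial likelihoods, rescaled per node.

    Returns (scaled partials D, log of the accumulated scale per node's
    subtree, per-edge transition matrices).
    """
    D = tipL.copy()
    logscale = np.zeros(tree.n_nodes)
    P_edge = [None] * tree.n_nodes
    for v in tree.postorder():
        if v != tree.root:
            P_edge[v] = er_transition_matrix(q, tree.lengths[v])
        if not tree.is_tip(v):
            acc = np.ones(_K)
            ls = 0.0
            for c in tree.children[v]:
                acc = acc * (P_edge[c] @ D[c])
                ls += logscale[c]
            m = acc.max()
            if m <= 0:
                raise FloatingPointError("zero partial likelihood")
            D[v] = acc / m
            logscale[v] = ls + np.log(m)
    return D, logscale, P_edge


def _log_likelihood(tree: Phylogeny, tipL: np.ndarray, q: float) -> float:
    D, logscale, _ = _prune(tree, tipL, q)
    pi = np.full(_K, 1.0 / _K)
    return float(np.log(pi @ D[tree.root]) + logscale[tree.root])


def ml_asr_bin(
    tree: Phylogeny,
    tip_states: Mapping[str, str],
    *,
    q_bounds: tuple[float, float] = Q_BOUNDS,
    xtol: float = 1e-8,
    unknown_as_ambiguous: bool = False,
) -> BinMLResult:
    """Fit the ER rate and compute marginal ancestral state probabilities.

    The rate ``q`` maximizes the pruning likelihood with a uniform root
    prior; node marginals combine the partial likelihood of each node's
    subtree with that of the rest of the tree (equivalent to re-rooting at
    the node).  When every tip shares one state the rate is unidentifiable
    and is pinned at the lower optimization bound with a warning.
    """
    if tree.n_tips < 2:
        raise ValueError("tree must have at least 2 tips")
    if not any(l > 0 for l in tree.lengths):
        raise ValueError("tree has no positive branch length")
    tipL = _tip_partials(tree, tip_states, unknown_as_ambiguous)

    observed = {tip_states[l] for l in tree.tip_labels}
    if len(observed) == 1:
        warnings.warn(
            "all tips share one state; ER rate unidentifiable, using lower bound",
            stacklevel=2,
        )
        q_hat = q_bounds[0]
    else:
        # the profile over q can be multimodal (e.g. a saturation plateau
        # competing with a low-rate peak): coarse grid scan, then refine
        lo, hi = np.log(q_bounds[0]), np.log(q_bounds[1])
        grid = np.linspace(lo, hi, 40)
        nll = [-_log_likelihood(tree, tipL, float(np.exp(x))) for x in grid]
        i = int(np.argmin(nll))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda x: -_log_likelihood(tree, tipL, float(np.exp(x))),
            bounds=(a, b),
            method="bounded",
            options={"xatol": xtol},
        )
        q_hat = float(np.exp(res.x)) if res.fun <= nll[i] else float(np.exp(grid[i]))

    loglik = _log_likelihood(tree, tipL, q_hat)
    marginals = _marginals(tree, tipL, q_hat)
    return BinMLResult(q=q_hat, marginals=marginals, log_likelihood=loglik)


def _marginals(
    tree: Phylogeny, tipL: np.ndarray, q: float
) -> dict[str, NodeMarginals]:
    D, _, P_edge = _prune(tree, tipL, q)
    pi = np.full(_K, 1.0 / _K)
    # "outside" likelihood U[v]: evidence from everything except v's subtree,
    # already transported to node v's statespace; root gets the prior.
    U = np.zeros_like(D)
    U[tree.root] = pi
    # cache child messages M_c(s_parent) = sum_sc P[s_parent, sc] D[c, sc]
    msg = [None] * tree.n_nodes
    for v in tree.postorder():
        if v != tree.root:
            msg[v] = P_edge[v] @ D[v]
    for v in tree.preorder():
        if tree.is_tip(v):
            continue
        for c in tree.children[v]:
            sib = np.ones(_K)
            for b in tree.children[v]:
                if b != c:
                    sib = sib * msg[b]
            above = U[v] * sib           # function of v's state
            U[c] = P_edge[c].T @ above   # transport to c's state
            m = U[c].max()
            if m > 0:
                U[c] /= m
    out: dict[str, NodeMarginals] = {}
    for v in range(tree.n_nodes):
        w = U[v] * D[v]
        out[tree.labels[v]] = NodeMarginals(tree.labels[v], w / w.sum())
    return out


_INF = np.inf


def parsimony_asr_bin(
    tree: Phylogeny, tip_states: Mapping[str, str]
) -> BinParsimonyResult:
    """Sankoff parsimony with unit cost between any two distinct states.

    Branch lengths are ignored.  The per-node state set contains every
    state attainable in at least one minimum-cost assignment (computed from
    the down-pass subtree costs plus an up-pass cost for the rest of the
    tree).
    """
    if tree.n_tips < 2:
        raise ValueError("tree must have at least 2 tips")
    tipL = _tip_partials(tree, tip_states)
    cost = 1.0 - np.eye(_K)  # unit cost matrix

    S = np.zeros((tree.n_nodes, _K))  # min cost of subtree given node state
    for v in tree.postorder():
        if tree.is_tip(v):
            S[v] = np.where(tipL[v] > 0, 0.0, _INF)
        else:
            for c in tree.children[v]:
                S[v] += np.min(cost + S[c][None, :], axis=1)
    total = float(S[tree.root].min())

    # R[v, s]: min cost of everything outside v's subtree given v in state s
    R = np.zeros((tree.n_nodes, _K))
    for v in tree.preorder():
        if tree.is_tip(v):
            continue
        for c in tree.children[v]:
            sib = np.zeros(_K)
            for b in tree.children[v]:
                if b != c:
                    sib += np.min(cost + S[b][None, :], axis=1)
            above = R[v] + sib
            R[c] = np.min(above[:, None] + cost, axis=0)

    sets: dict[str, frozenset[str]] = {}
    for v in range(tree.n_nodes):
        T = S[v] + R[v]
        admissible = frozenset(
            STATES[i] for i in range(_K) if T[i] <= total + 1e-9
        )
        sets[tree.labels[v]] = admissible
    return BinParsimonyResult(cost=total, state_sets=sets)


DEFAULT_TIE_TOL = 0.05


def call_state_ml(probs: np.ndarray, tie_tol: float = DEFAULT_TIE_TOL) -> str:
    """Discrete call from ML marginals: argmax, or ``?`` on a near-tie."""
    p = np.asarray(probs, dtype=float)
    order = np.argsort(p)[::-1]
    if p[order[0]] - p[order[1]] < tie_tol:
        return UNKNOWN
    return STATES[order[0]]


def call_state_parsimony(state_set: frozenset[str]) -> str:
    """Discrete call from a parsimony state set: singleton, else ``?``."""
    if len(state_set) == 1:
        return next(iter(state_set))
    return UNKNOWN


def smooth_reconstruction(vector: CharacterVector) -> CharacterVector:
    """Fill every bin strictly inside the suitable span with ``1``.

    Reconstructed suitable ranges must not be interrupted by unsuitable or
    unknown bins (unimodal response); idempotent, never removes a ``1``.
    A vector with no suitable bin is returned unchanged with a warning.
    """
    span = vector.suitable_span()
    if span is None:
        warnings.warn(
            f"{vector.species_id}: no suitable bin to smooth", stacklevel=2
        )
        return vector
    first, last = span
    states = tuple(
        SUITABLE if first <= i <= last else s for i, s in enumerate(vector.states)
    )
    return CharacterVector(vector.species_id, vector.scheme, states)


@dataclass
class ReconstructionResult:
    """Per-node BAR reconstruction across all bins of a matrix."""

    method: str                                   # "ml" | "parsimony"
    scheme: BinScheme
    node_ids: list[str]                           # internal nodes, postorder
    raw: dict[str, CharacterVector]
    smoothed: dict[str, CharacterVector]
    q_per_bin: list[float] | None = None          # ml only
    log_likelihood_per_bin: list[float] | None = None
    marginals: dict[str, np.ndarray] | None = None  # node -> (n_bins, 3), ml only
    cost_per_bin: list[float] | None = None       # parsimony only


def reconstruct_matrix(
    tree: Phylogeny,
    matrix: CharacterMatrix,
    method: str = "ml",
    *,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> ReconstructionResult:
    """Run per-bin ancestral reconstruction over a whole character matrix.

    Bins are independent characters; the per-node bin vectors assembled
    from the per-bin calls are smoothed into contiguous suitable runs.
    """
    if method not in ("ml", "parsimony"):
        raise ValueError(f"unknown method {method!r}")
    tips = set(tree.tip_labels)
    species = set(matrix.species_ids)
    if tips != species:
        only_tree = sorted(tips - species)
        only_matrix = sorted(species - tips)
        raise ValueError(
            f"tree tips and matrix species differ; only in tree: {only_tree}, "
            f"only in matrix: {only_matrix}"
        )

    internal = [tree.labels[v] for v in tree.internal_indices]
    n_bins = matrix.scheme.n_bins
    calls: dict[str, list[str]] = {nid: [] for nid in internal}
    q_per_bin: list[float] = []
    ll_per_bin: list[float] = []
    cost_per_bin: list[float] = []
    marg: dict[str, np.ndarray] = {nid: np.zeros((n_bins, _K)) for nid in internal}

    for j in range(n_bins):
        tip_states = {r.species_id: r.states[j] for r in matrix.rows}
        if method == "ml":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # monomorphic bins are routine here
                res = ml_asr_bin(tree, tip_states)
            q_per_bin.append(res.q)
            ll_per_bin.append(res.log_likelihood)
            for nid in internal:
                p = res.marginals[nid].probs
                marg[nid][j] = p
                calls[nid].append(call_state_ml(p, tie_tol))
        else:
            res = parsimony_asr_bin(tree, tip_states)
            cost_per_bin.append(res.cost)
            for nid in internal:
                calls[nid].append(call_state_parsimony(res.state_sets[nid]))

    raw = {
        nid: CharacterVector(nid, matrix.scheme, tuple(states))
        for nid, states in calls.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nodes with no suitable bin pass through
        smoothed = {nid: smooth_reconstruction(v) for nid, v in raw.items()}
    return ReconstructionResult(
        method=method,
        scheme=matrix.scheme,
        node_ids=internal,
        raw=raw,
        smoothed=smoothed,
        q_per_bin=q_per_bin if method == "ml" else None,
        log_likelihood_per_bin=ll_per_bin if method == "ml" else None,
        marginals=marg if method == "ml" else None,
        cost_per_bin=cost_per_bin if method == "parsimony" else None,
    )


RETAINED_SUITABLE = "retained-suitable"
RETAINED_UNSUITABLE = "retained-unsuitable"
GAINED = "gained"
LOST = "lost"
INDETERMINATE = "indeterminate"


def compare_tip_to_ancestor(
    tip: CharacterVector | Sequence[str], ancestor: CharacterVector | Sequence[str]
) -> tuple[list[str], str]:
    """Classify per-bin change from an ancestor to a tip (or any descendant).

    Returns per-bin labels and a branch summary: "reduction" when bins were
    only lost, "expansion" when only gained, "stable" when neither, "mixed"
    when both.
    """
    t = tip.states if isinstance(tip, CharacterVector) else tuple(tip)
    a = ancestor.states if isinstance(ancestor, CharacterVector) else tuple(ancestor)
    if len(t) != len(a):
        raise ValueError("tip and ancestor vectors differ in length")
    labels = []
    for ts, as_ in zip(t, a):
        if UNKNOWN in (ts, as_):
            labels.append(INDETERMINATE)
        elif ts == SUITABLE and as_ == SUITABLE:
            labels.append(RETAINED_SUITABLE)
        elif ts == UNSUITABLE and as_ == UNSUITABLE:
            labels.append(RETAINED_UNSUITABLE)
        elif ts == SUITABLE:  # suitable now, not in the ancestor
            labels.append(GAINED)
        else:
            labels.append(LOST)
    gained = labels.count(GAINED)
    lost = labels.count(LOST)
    if lost and not gained:
        summary = "reduction"
    elif gained and not lost:
        summary = "expansion"
    elif not gained and not lost:
        summary = "stable"
    else:
        summary = "mixed"
    return labels, summary
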