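"""Phylogenetic likelihoods of pillar data and posterior decoding.

Per pillar and per assignment vector, the likelihood of the observed slot
occupancies is computed by Felsenstein pruning over the species tree under
the four-state loss model, with the WGD root fixed in state U.  Pillars are
then chained along the ancestral gene order by a hidden Markov model whose
hidden state is the assignment vector; consecutive pillars share their
assignment except for rare switches (probability theta per genome per
junction, 1/2 across double synteny breaks).

The pruning pass shares partial likelihoods between assignment vectors: a
subtree spanning k genomes only distinguishes 2^k local assignment patterns,
so the full (m, 2^n) emission table costs far less than 2^n independent
prunings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _hmmcore
from .model import F, N_STATES, S1, S2, U, LossParams, transition_probs
from .pillars import (JunctionModel, PillarSet, PosteriorTable, n_vectors)
from .trees import LossTree

# TIP_TABLE[obs, bit, state]: conditional likelihood of the genome's slot data
# given the tip state, for assignment bit 0 (v_g = 1) or 1 (v_g = 2).
# duplicated -> U or F; a single survivor in slot p1 is the subgenome-v_g copy,
# a survivor in slot p2 the copy from the other subgenome.
TIP_TABLE = np.zeros((3, 2, N_STATES))
TIP_TABLE[0, :, U] = 1.0
TIP_TABLE[0, :, F] = 1.0
TIP_TABLE[1, 0, S1] = 1.0
TIP_TABLE[1, 1, S2] = 1.0
TIP_TABLE[2, 0, S2] = 1.0
TIP_TABLE[2, 1, S1] = 1.0


def tip_likelihood(obs_code: int, v_g: int) -> np.ndarray:
    """State likelihood vector (U, F, S1, S2) for one genome's observation."""
    if obs_code not in (0, 1, 2):
        raise ValueError(f"invalid observation code {obs_code!r}")
    if v_g not in (1, 2):
        raise ValueError(f"assignment must be 1 or 2, got {v_g!r}")
    return TIP_TABLE[obs_code, v_g - 1].copy()


def edge_transition_matrices(tree: LossTree, params: LossParams,
                             eps_early: float | None = None,
                             early_mask: np.ndarray | None = None) -> np.ndarray:
    """(n_edges, 4, 4) transition matrices, optionally with a distinct
    fractionation bias ``eps_early`` on the root-proximal branch class."""
    P = np.empty((tree.n_edges, N_STATES, N_STATES))
    if eps_early is not None and early_mask is None:
        early_mask = tree.early_edge_mask()
    for e in range(tree.n_edges):
        eps = params.epsilon
        if eps_early is not None and early_mask[e]:
            eps = eps_early
        P[e] = transition_probs(params.gamma, eps, tree.edge_lengths[e])
    return P


def _genome_index(tree: LossTree, genomes: tuple[str, ...]) -> dict[int, int]:
    """Map tip node -> column index in the pillar table."""
    if set(genomes) != set(tree.taxa):
        raise ValueError(
            f"tree taxa {tree.taxa} do not match pillar genomes {tuple(genomes)}")
    col = {name: i for i, name in enumerate(genomes)}
    return {nd: col[tree.tip_labels[nd]] for nd in range(tree.n_nodes)
            if tree.is_tip[nd]}


def emission_matrix(pillar_set: PillarSet, tree: LossTree,
                    edge_P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pillar per-assignment-vector likelihoods.

    Returns ``(E, log_scale)`` where E is (m, 2^n) with each row scaled to a
    maximum of 1 and ``log_scale`` holds the per-row log of the scaling
    factor, so log P(pillar i | v) = log E[i, v] + log_scale[i].
    """
    obs = pillar_set.obs
    m, n = obs.shape
    V = n_vectors(n)
    tipcol = _genome_index(tree, pillar_set.genomes)

    # message[node] = (tips, arr) with arr of shape (2^k, m, 4); pattern bit j
    # encodes the assignment of genome tips[j].
    msgs: dict[int, tuple[list[int], np.ndarray]] = {}
    for node in range(tree.n_nodes):  # postorder by construction
        if tree.is_tip[node]:
            g = tipcol[node]
            arr = TIP_TABLE[obs[:, g]]            # (m, 2, 4)
            arr = np.ascontiguousarray(arr.transpose(1, 0, 2))  # (2, m, 4)
            tips = [g]
        else:
            tips, arr = None, None
            for c in tree.children[node]:
                ctips, carr = msgs.pop(c)
                if arr is None:
                    tips, arr = ctips, carr
                else:
                    # combined pattern index: the new child's bits sit above
                    # the existing block, so combined = p_new * 2^k1 + p_old
                    arr = (carr[:, None] * arr[None, :]).reshape(-1, m, N_STATES)
                    tips = tips + ctips
        # edge above this node (the seed node's edge is the WGD stem)
        arr = arr @ edge_P[node].T
        msgs[node] = (tips, arr)

    tips, arr = msgs.pop(tree.seed)
    E_pat = arr[:, :, U]                           # root distribution delta_U
    # pattern bit j belongs to genome tips[j]; re-index so bit g = genome g
    pat = np.arange(E_pat.shape[0])
    idx = np.zeros_like(pat)
    for j, g in enumerate(tips):
        idx |= ((pat >> j) & 1) << g
    E = np.empty((m, V))
    E[:, idx] = E_pat.T
    scale = E.max(axis=1)
    safe = np.where(scale > 0, scale, 1.0)
    E /= safe[:, None]
    with np.errstate(divide="ignore"):
        log_scale = np.log(np.where(scale > 0, scale, 0.0))
    return E, log_scale


def _flip_matrix(junctions: JunctionModel, m: int) -> np.ndarray:
    """(m-1, n) per-junction per-genome flip probabilities."""
    flags = junctions.double_breaks
    if flags.shape[0] != m - 1:
        raise ValueError("junction flags do not match pillar count")
    flips = np.full(flags.shape, junctions.theta, dtype=float)
    flips[flags] = 0.5
    return flips


def junction_transition(junctions: JunctionModel, junction: int) -> np.ndarray:
    """Dense (2^n, 2^n) assignment-vector transition kernel at one junction.

    The kernel is the tensor product of independent per-genome 2x2 flip
    kernels; rows sum to 1.
    """
    flags = junctions.double_breaks[junction]
    n = flags.shape[0]
    K = np.ones((1, 1))
    for g in range(n):
        t = 0.5 if flags[g] else junctions.theta
        Kg = np.array([[1.0 - t, t], [t, 1.0 - t]])
        K = np.kron(Kg, K)  # genome g occupies bit g
    return K


def pillar_loglik(pillar_set: PillarSet, index: int, assignment_index: int,
                  tree: LossTree, edge_P: np.ndarray) -> float:
    """Log-likelihood of one pillar under one fixed assignment vector."""
    single = pillar_set.subset(index, index + 1)
    E, log_scale = emission_matrix(single, tree, edge_P)
    val = E[0, assignment_index]
    if val <= 0:
        return -np.inf
    return float(np.log(val) + log_scale[0])


def sequence_loglik(pillar_set: PillarSet, tree: LossTree, params: LossParams,
                    junctions: JunctionModel, *,
                    edge_P: np.ndarray | None = None) -> float:
    """Total log-likelihood of the ordered pillar set (forward algorithm).

    The hidden chain starts from the uniform distribution over the 2^n
    assignment vectors.
    """
    if edge_P is None:
        edge_P = edge_transition_matrices(tree, params)
    E, log_scale = emission_matrix(pillar_set, tree, edge_P)
    flips = _flip_matrix(junctions, pillar_set.m)
    ll, _ = _hmmcore.forward(E, flips)
    return float(ll + log_scale.sum())


def posterior_assignments(pillar_set: PillarSet, tree: LossTree,
                          params: LossParams, junctions: JunctionModel, *,
                          edge_P: np.ndarray | None = None) -> PosteriorTable:
    """Forward-backward posterior over assignment vectors at every pillar."""
    if edge_P is None:
        edge_P = edge_transition_matrices(tree, params)
    E, log_scale = emission_matrix(pillar_set, tree, edge_P)
    flips = _flip_matrix(junctions, pillar_set.m)
    ll, alpha = _hmmcore.forward(E, flips)
    beta = _hmmcore.backward(E, flips)
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    n = pillar_set.n_genomes
    V = post.shape[1]
    bit = (np.arange(V)[:, None] >> np.arange(n)[None, :]) & 1  # (V, n)
    marginals = post @ (bit == 0)  # P(v_g = 1)
    return PosteriorTable(genomes=pillar_set.genomes, vector_probs=post,
                          marginals=marginals,
                          loglik=float(ll + log_scale.sum()))


def expected_loss_counts(pillar_set: PillarSet, tree: LossTree,
                         params: LossParams, junctions: JunctionModel, *,
                         edge_P: np.ndarray | None = None,
                         posterior: PosteriorTable | None = None) -> pd.DataFrame:
    """Expected per-branch counts of resolutions out of state U.

    Because S1, S2 and F are absorbing, a loss to S1 happened on a branch iff
    the branch's parent node is in U and its child in S1 (likewise S2 and
    fixation F).  Expected counts are posterior-weighted sums over pillars
    and assignment vectors of the joint parent/child state probabilities,
    computed by an inside-outside pass.  The per-branch ratio of expected S2
    to S1 losses (NaN when E[S1] = 0) estimates the retention ratio of
    subgenome 2 relative to subgenome 1 on that branch.
    """
    if edge_P is None:
        edge_P = edge_transition_matrices(tree, params)
    if posterior is None:
        posterior = posterior_assignments(pillar_set, tree, params, junctions,
                                          edge_P=edge_P)
    w = posterior.vector_probs  # (m, V)
    obs = pillar_set.obs
    m, n = obs.shape
    V = n_vectors(n)
    tipcol = _genome_index(tree, pillar_set.genomes)
    bits = (np.arange(V)[:, None] >> np.arange(n)[None, :]) & 1

    # inside: L[node][v, m, s] = P(data below node | state at node = s)
    inside: list[np.ndarray | None] = [None] * tree.n_nodes
    up_msg: list[np.ndarray | None] = [None] * tree.n_nodes
    for node in range(tree.n_nodes):
        if tree.is_tip[node]:
            g = tipcol[node]
            L = TIP_TABLE[obs[None, :, g], bits[:, g, None]]  # (V, m, 4)
        else:
            L = np.ones((V, m, N_STATES))
            for c in tree.children[node]:
                L = L * up_msg[c]
        inside[node] = L
        up_msg[node] = L @ edge_P[node].T

    Z = (up_msg[tree.seed])[:, :, U]  # (V, m) total likelihood per vector
    invZ = np.where(Z > 0, 1.0 / np.where(Z > 0, Z, 1.0), 0.0)

    # outside: H[node][v, m, s] = P(data above node, state at node = s)
    H: list[np.ndarray | None] = [None] * tree.n_nodes
    seed_top = np.zeros((V, m, N_STATES))
    seed_top[:, :, U] = 1.0  # WGD root is in U with certainty
    rows = []
    # process nodes parent-before-child (reverse postorder)
    for node in range(tree.n_nodes - 1, -1, -1):
        if node == tree.seed:
            top = seed_top
        else:
            p = tree.parent[node]
            sib = np.ones((V, m, N_STATES))
            for c in tree.children[p]:
                if c != node:
                    sib = sib * up_msg[c]
            top = H[p] * sib
        # joint over the edge above `node`: top[a] * P[a, x] * inside[x]
        P = edge_P[node]
        exp_counts = {}
        for state, name in ((S1, "S1"), (S2, "S2"), (F, "F")):
            joint = top[:, :, U] * P[U, state] * inside[node][:, :, state] * invZ
            exp_counts[name] = float((w * joint.T).sum())
        e1, e2 = exp_counts["S1"], exp_counts["S2"]
        rows.append({
            "branch": tree.edge_label(node),
            "length": tree.edge_lengths[node],
            "expected_S1": exp_counts["S1"],
            "expected_S2": exp_counts["S2"],
            "expected_F": exp_counts["F"],
            "s2_s1_ratio": (e2 / e1) if e1 > 0 else np.nan,
        })
        H[node] = top @ P  # H at node itself, for its children
    return pd.DataFrame(rows)


def block_segmentation(posterior: PosteriorTable, junctions: JunctionModel,
                       confidence: float = 0.85,
                       min_genomes: int | None = None) -> list[tuple[int, int]]:
    """Maximal runs of pillars with consistent high-confidence assignments.

    Two consecutive pillars are linked when at least ``min_genomes`` genomes
    have the same subgenome assignment on both sides, each at posterior
    confidence >= ``confidence``; a junction where every genome has a double
    synteny break always separates blocks.  Returns half-open (start, stop)
    pillar spans.
    """
    n = posterior.n_genomes
    if min_genomes is None:
        min_genomes = n
    if not (1 <= min_genomes <= n):
        raise ValueError(f"min_genomes must be in [1, {n}], got {min_genomes}")
    marg = posterior.marginals
    label1 = marg >= 0.5
    conf = np.maximum(marg, 1.0 - marg)
    ok = conf >= confidence
    agree = ok[:-1] & ok[1:] & (label1[:-1] == label1[1:])  # (m-1, n)
    linked = agree.sum(axis=1) >= min_genomes
    linked &= ~junctions.double_breaks.all(axis=1)
    blocks = []
    start = 0
    for i, lnk in enumerate(linked):
        if not lnk:
            blocks.append((start, i + 1))
            start = i + 1
    blocks.append((start, posterior.m))
    return blocks
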