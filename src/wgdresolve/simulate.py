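"""Synthetic post-WGD pillar data with known ground truth.

The generator is the probabilistic model read forwards: every ancestral locus
starts in state U at the WGD root and evolves independently down the tree
under the four-state loss process; each genome's hidden subgenome assignment
forms a Markov chain along the ancestral order, flipping with probability
theta per junction (1/2 at planted double synteny breaks); the tip state plus
the assignment determine which slot holds each surviving gene.  All outputs
are reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import F, S1, S2, U, LossParams
from .pillars import OBS_DUPLICATED, OBS_SINGLE_P1, OBS_SINGLE_P2, PillarSet
from .likelihood import edge_transition_matrices
from .trees import LossTree


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Branch lengths live on the tree (alpha*t units).  ``eps_early`` activates
    a distinct fractionation bias on the root-proximal branch class (the
    temporal-bias scenario); ``double_break_rate`` is the per-genome
    per-junction probability of a planted double synteny break.
    """

    tree: str
    m: int
    gamma: float
    epsilon: float
    theta: float
    seed: int
    eps_early: float | None = None
    double_break_rate: float = 0.02

    def loss_params(self) -> LossParams:
        return LossParams(gamma=self.gamma, epsilon=self.epsilon)


@dataclass
class SimResult:
    pillar_set: PillarSet
    tree: LossTree
    config: SimConfig
    tip_states: np.ndarray        # (m, n) in {U,F,S1,S2} codes
    node_states: np.ndarray       # (m, n_nodes) full truth
    assignments: np.ndarray       # (m, n) in {1,2}
    branch_events: pd.DataFrame   # realized per-branch loss/fixation counts


def _example_newick(n: int, stem: float = 0.5) -> str:
    """A caterpillar tree with varied, plausible branch lengths."""
    names = [f"g{i+1}" for i in range(n)]
    tip_lens = [round(0.2 + 0.05 * (i % 4), 2) for i in range(n)]
    if n == 1:
        return f"({names[0]}:{tip_lens[0]}):{stem};"
    sub = f"{names[0]}:{tip_lens[0]}"
    for i in range(1, n):
        sub = f"({sub},{names[i]}:{tip_lens[i]}):0.15"
    # outermost ":0.15" is replaced by the stem length
    sub = sub.rsplit(":", 1)[0]
    return f"{sub}:{stem};"


def example_config(n_genomes: int = 6, m: int = 5000, gamma: float = 0.17,
                   epsilon: float = 0.65, theta: float = 0.005, seed: int = 0,
                   **kw) -> SimConfig:
    """Default study conditions: a plant-like polyploid clade."""
    return SimConfig(tree=_example_newick(n_genomes), m=m, gamma=gamma,
                     epsilon=epsilon, theta=theta, seed=seed, **kw)


def simulate_states(config: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[LossTree, np.ndarray, pd.DataFrame]:
    """Evolve per-pillar states down the tree; returns (tree, node_states,
    realized branch events)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree = LossTree.from_newick(config.tree)
    early = tree.early_edge_mask() if config.eps_early is not None else None
    edge_P = edge_transition_matrices(tree, config.loss_params(),
                                      eps_early=config.eps_early,
                                      early_mask=early)
    m = config.m
    states = np.empty((m, tree.n_nodes), dtype=np.int8)
    events = []
    # parent-before-child; the seed node's parent is the WGD root in state U
    for node in range(tree.n_nodes - 1, -1, -1):
        parent_state = (np.full(m, U, dtype=np.int8) if node == tree.seed
                        else states[:, tree.parent[node]])
        cum = edge_P[node].cumsum(axis=1)
        u = rng.random(m)
        child = (u[:, None] > cum[parent_state]).sum(axis=1).astype(np.int8)
        states[:, node] = child
        from_u = parent_state == U
        events.append({
            "branch": tree.edge_label(node),
            "losses_S1": int(((child == S1) & from_u).sum()),
            "losses_S2": int(((child == S2) & from_u).sum()),
            "fixations": int(((child == F) & from_u).sum()),
        })
    return tree, states, pd.DataFrame(events)


def simulate_pillars(config: SimConfig, tree: LossTree, node_states: np.ndarray,
                     rng: np.random.Generator | None = None) -> SimResult:
    """Attach assignment chains, breaks and slot observations to tip states."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    m = config.m
    n = len(tree.taxa)
    genomes = tree.taxa
    tip_nodes = {tree.tip_labels[i]: i for i in range(tree.n_nodes)
                 if tree.is_tip[i]}
    tips = np.column_stack([node_states[:, tip_nodes[g]] for g in genomes])

    breaks = rng.random((max(m - 1, 0), n)) < config.double_break_rate
    flip_p = np.full((max(m - 1, 0), n), config.theta)
    flip_p[breaks] = 0.5
    v = np.empty((m, n), dtype=np.int8)
    v[0] = rng.integers(1, 3, size=n)
    if m > 1:
        flips = rng.random((m - 1, n)) < flip_p
        for i in range(1, m):
            v[i] = np.where(flips[i - 1], 3 - v[i - 1], v[i - 1])

    obs = np.empty((m, n), dtype=np.int8)
    obs[(tips == U) | (tips == F)] = OBS_DUPLICATED
    # a surviving S1 copy sits in slot p1 iff the slot-1 track IS subgenome 1
    s1 = tips == S1
    s2 = tips == S2
    obs[s1] = np.where(v[s1] == 1, OBS_SINGLE_P1, OBS_SINGLE_P2)
    obs[s2] = np.where(v[s2] == 1, OBS_SINGLE_P2, OBS_SINGLE_P1)

    anchors = np.array([f"anc{i:05d}" for i in range(m)], dtype=object)
    genes = np.empty((m, n, 2), dtype=object)
    for g, name in enumerate(genomes):
        # subgenome of the slot-1 track is v[:, g]; slot-2 the complement
        sub_of_slot = np.stack([v[:, g], 3 - v[:, g]], axis=1)  # (m, 2)
        for k in range(2):
            ids = np.array([f"{name}_s{sub_of_slot[i, k]}_{i:05d}"
                            for i in range(m)], dtype=object)
            occupied = np.where(
                obs[:, g] == OBS_DUPLICATED, True,
                (obs[:, g] == OBS_SINGLE_P1) == (k == 0))
            genes[:, g, k] = np.where(occupied, ids, None)

    pillar_set = PillarSet(genomes=genomes, anchors=anchors, obs=obs,
                           double_breaks=breaks, genes=genes)
    return SimResult(pillar_set=pillar_set, tree=tree, config=config,
                     tip_states=tips, node_states=node_states, assignments=v,
                     branch_events=pd.DataFrame())


def simulate_dataset(config: SimConfig) -> SimResult:
    """One-call generator: states + assignment chains + observations."""
    rng = np.random.default_rng(config.seed)
    tree, node_states, events = simulate_states(config, rng)
    result = simulate_pillars(config, tree, node_states, rng)
    result.branch_events = events
    return result


# ------------------------------------------------------------------ genomes

def simulate_genomes(config: SimConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, SimResult]:
    """Raw inputs for the synteny pipeline: gene orders and homolog tables.

    Each polyploid genome gets two chromosomes, one per parental subgenome,
    carrying the surviving genes in ancestral order (no rearrangement).  The
    outgroup carries the anchor genes on one chromosome.  Returns
    (gene-order table, homolog-candidate table, truth).
    """
    result = simulate_dataset(config)
    m = config.m
    rows = []
    rows += [{"genome": "outgroup", "chromosome": "chr1", "position": i,
              "gene_id": result.pillar_set.anchors[i]} for i in range(m)]
    homologs = []
    for g, name in enumerate(result.tree.taxa):
        for sub in (1, 2):
            pos = 0
            for i in range(m):
                state = result.tip_states[i, g]
                survives = state in (U, F) or state == (S1 if sub == 1 else S2)
                if survives:
                    gid = f"{name}_s{sub}_{i:05d}"
                    rows.append({"genome": name, "chromosome": f"sub{sub}",
                                 "position": pos, "gene_id": gid})
                    homologs.append({"genome": name,
                                     "anchor": result.pillar_set.anchors[i],
                                     "candidate": gid})
                    pos += 1
    orders = pd.DataFrame(rows)
    return orders, pd.DataFrame(homologs), result


# ------------------------------------------------------------------ network

def simulate_interaction_network(gene_ids: np.ndarray, labels: np.ndarray,
                                 n_edges: int, crossing_depletion: float,
                                 seed: int) -> pd.DataFrame:
    """Random interaction edges among labeled single-copy genes.

    Candidate pairs are drawn uniformly; a pair whose endpoints carry
    different subgenome labels is kept with probability
    ``crossing_depletion`` (1 = no depletion, 0 = no crossing edges).
    """
    if not (0.0 <= crossing_depletion <= 1.0):
        raise ValueError("crossing_depletion must lie in [0, 1]")
    gene_ids = np.asarray(gene_ids, dtype=object)
    labels = np.asarray(labels)
    if len(gene_ids) < 2:
        raise ValueError("need at least two labeled genes")
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, int]] = set()
    edges = []
    max_tries = 1000 * n_edges + 1000
    tries = 0
    while len(edges) < n_edges:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not draw the requested number of edges")
        i, j = rng.integers(0, len(gene_ids), size=2)
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in chosen:
            continue
        if labels[i] != labels[j] and rng.random() > crossing_depletion:
            continue
        chosen.add(key)
        edges.append({"gene_a": gene_ids[key[0]], "gene_b": gene_ids[key[1]]})
    return pd.DataFrame(edges)
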