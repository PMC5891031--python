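"""Tests for depletion of protein interactions across subgenomes.

If biased fractionation reflects conflicts between co-evolved gene modules
inherited from the two allopolyploid parents, single-copy genes whose
products physically interact should preferentially derive from the *same*
parental subgenome.  The test counts "crossing" interaction edges (endpoints
labeled with different subgenomes) and compares the observed count to a null
obtained by shuffling subgenome labels across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pillars import OBS_SINGLE_P1, OBS_SINGLE_P2, PillarSet, PosteriorTable


def _edge_indices(edges: pd.DataFrame, gene_index: dict) -> np.ndarray:
    missing = [g for col in ("gene_a", "gene_b") for g in edges[col]
               if g not in gene_index]
    if missing:
        raise ValueError(f"unlabeled edge endpoint(s): {sorted(set(missing))[:5]}")
    a = edges["gene_a"].map(gene_index).to_numpy()
    b = edges["gene_b"].map(gene_index).to_numpy()
    if (a == b).any():
        raise ValueError("self-edges are not allowed")
    return np.column_stack([a, b])


def crossing_count(edges: pd.DataFrame, labels: pd.Series) -> int:
    """Number of edges whose endpoints carry different subgenome labels."""
    lab = labels.to_dict()
    idx = _edge_indices(edges, {g: i for i, g in enumerate(labels.index)})
    arr = labels.to_numpy()
    return int((arr[idx[:, 0]] != arr[idx[:, 1]]).sum())


def randomization_test(edges: pd.DataFrame, labels: pd.Series,
                       n_rand: int = 1000, seed: int = 0
                       ) -> tuple[int, float, float]:
    """One-sided permutation test for a deficit of crossing interactions.

    Subgenome labels are shuffled across genes (the label multiset is
    preserved) ``n_rand`` times; the add-one p-value
    ``(1 + #{null <= observed}) / (1 + n_rand)`` is small when crossing
    edges are rarer than exchangeability predicts.

    Returns (observed crossing count, null mean, p).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if len(edges) == 0:
        raise ValueError("need at least one edge")
    arr = labels.to_numpy()
    if len(np.unique(arr)) < 2:
        return crossing_count(edges, labels), float("nan"), float("nan")
    idx = _edge_indices(edges, {g: i for i, g in enumerate(labels.index)})
    observed = int((arr[idx[:, 0]] != arr[idx[:, 1]]).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand, dtype=np.int64)
    for r in range(n_rand):
        perm = rng.permutation(arr)
        null[r] = (perm[idx[:, 0]] != perm[idx[:, 1]]).sum()
    p = (1.0 + (null <= observed).sum()) / (1.0 + n_rand)
    return observed, float(null.mean()), float(p)


def single_copy_gene_table(pillar_set: PillarSet,
                           posterior: PosteriorTable) -> pd.DataFrame:
    """Subgenome label and assignment confidence for every single-copy gene.

    A gene surviving in slot p1 derives from subgenome v_g, one in slot p2
    from the other subgenome; the posterior marginal of v_g therefore gives
    P(gene from subgenome 1).  Label is the argmax, confidence its
    probability (in [0.5, 1]).
    """
    if pillar_set.genes is None:
        raise ValueError("pillar set carries no gene identifiers")
    rows = []
    for i in range(pillar_set.m):
        for g in range(pillar_set.n_genomes):
            code = pillar_set.obs[i, g]
            if code == OBS_SINGLE_P1:
                gene = pillar_set.genes[i, g, 0]
                p1 = posterior.marginals[i, g]
            elif code == OBS_SINGLE_P2:
                gene = pillar_set.genes[i, g, 1]
                p1 = 1.0 - posterior.marginals[i, g]
            else:
                continue
            label = 1 if p1 >= 0.5 else 2
            rows.append({"gene": gene, "genome": pillar_set.genomes[g],
                         "pillar": i, "label": label,
                         "confidence": max(p1, 1.0 - p1)})
    return pd.DataFrame(rows, columns=["gene", "genome", "pillar", "label",
                                       "confidence"])


def confidence_sweep(edges: pd.DataFrame, gene_table: pd.DataFrame,
                     thresholds, n_rand: int = 1000, seed: int = 0
                     ) -> pd.DataFrame:
    """Crossing-interaction test restricted to increasingly confident genes.

    At each threshold, only single-copy genes with assignment confidence >=
    the threshold are kept; edges with both endpoints kept are tested.  The
    reported ratio is crossing-edge count over same-subgenome-edge count.
    Thresholds leaving fewer than two labeled genes or no testable edges
    yield empty rows (NaN).
    """
    rows = []
    for t in thresholds:
        if not (0.5 < t <= 1.0):
            raise ValueError(f"thresholds must lie in (0.5, 1], got {t}")
        sub = gene_table[gene_table["confidence"] >= t]
        labels = pd.Series(sub["label"].to_numpy(), index=sub["gene"])
        keep = (edges["gene_a"].isin(labels.index)
                & edges["gene_b"].isin(labels.index))
        sub_edges = edges[keep]
        row = {"threshold": t, "n_genes": len(labels), "n_edges": len(sub_edges),
               "observed": np.nan, "null_mean": np.nan, "p": np.nan,
               "crossing_ratio": np.nan}
        if len(labels) >= 2 and len(sub_edges) > 0 and labels.nunique() == 2:
            obs, mean, p = randomization_test(sub_edges, labels, n_rand, seed)
            same = len(sub_edges) - obs
            row.update(observed=obs, null_mean=mean, p=p,
                       crossing_ratio=(obs / same) if same > 0 else np.inf)
        rows.append(row)
    return pd.DataFrame(rows)
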