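"""Tab-separated file formats for gene orders, pillars and posteriors.

All tabular artifacts are TSV with a header row; trees are newick; fit
reports are JSON.  Gene positions are ranks within the analysis set (values
need not be dense; rank order is used).  Pillar files carry one row per
pillar in ancestral order: the outgroup anchor, per-genome slot genes (empty
cell = empty slot) and the per-genome double-break flag for the junction
*after* the row (last row: 0).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .pillars import (OBS_DUPLICATED, OBS_SINGLE_P1, OBS_SINGLE_P2, PillarSet,
                      PosteriorTable)
from .synteny import GenomeAnnotation


def read_gene_orders(path) -> dict[str, GenomeAnnotation]:
    """Read a (genome, chromosome, position, gene_id) TSV into per-genome
    annotations.  Positions are ranked per chromosome; duplicate gene ids
    within a genome are an error."""
    df = pd.read_csv(path, sep="\t", dtype={"genome": str, "chromosome": str,
                                            "gene_id": str})
    required = {"genome", "chromosome", "position", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene-order file missing column(s) {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["position"]):
        bad = df[pd.to_numeric(df["position"], errors="coerce").isna()]
        raise ValueError(f"non-numeric position(s), first at file row "
                         f"{bad.index[0] + 2}")
    out = {}
    for genome, sub in df.groupby("genome", sort=True):
        dup = sub["gene_id"][sub["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id {dup.iloc[0]!r} in genome "
                             f"{genome!r}")
        chroms = {}
        for chrom, rows in sub.groupby("chromosome", sort=True):
            chroms[chrom] = list(rows.sort_values("position", kind="stable")["gene_id"])
        out[genome] = GenomeAnnotation(chroms)
    return out


# ------------------------------------------------------------------ pillars

def write_pillars(pillar_set: PillarSet, path) -> None:
    genomes = pillar_set.genomes
    m = pillar_set.m
    genes = pillar_set.genes
    if genes is None:
        # synthesize stable slot identifiers from the anchor
        genes = np.empty((m, len(genomes), 2), dtype=object)
        for i in range(m):
            for g, name in enumerate(genomes):
                occ = {OBS_DUPLICATED: (True, True), OBS_SINGLE_P1: (True, False),
                       OBS_SINGLE_P2: (False, True)}[pillar_set.obs[i, g]]
                for k in (0, 1):
                    genes[i, g, k] = (f"{pillar_set.anchors[i]}.{name}.p{k+1}"
                                      if occ[k] else None)
    data = {"order_index": np.arange(m), "anchor": pillar_set.anchors}
    for g, name in enumerate(genomes):
        data[f"{name}.p1"] = genes[:, g, 0]
        data[f"{name}.p2"] = genes[:, g, 1]
    for g, name in enumerate(genomes):
        flags = np.zeros(m, dtype=int)
        if m > 1:
            flags[:-1] = pillar_set.double_breaks[:, g].astype(int)
        data[f"{name}.double_break"] = flags
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_pillars(path) -> PillarSet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("order_index", "anchor"):
        if col not in df.columns:
            raise ValueError(f"pillar file missing required column {col!r}")
    genomes = tuple(c[:-3] for c in df.columns if c.endswith(".p1"))
    if not genomes:
        raise ValueError("pillar file has no per-genome slot columns (*.p1)")
    for name in genomes:
        for suffix in (".p2", ".double_break"):
            if name + suffix not in df.columns:
                raise ValueError(f"pillar file missing column {name + suffix!r}")
    df = df.sort_values("order_index", key=lambda s: s.astype(int),
                        kind="stable").reset_index(drop=True)
    m, n = len(df), len(genomes)
    obs = np.empty((m, n), dtype=np.int8)
    genes = np.empty((m, n, 2), dtype=object)
    for g, name in enumerate(genomes):
        p1 = df[f"{name}.p1"].replace("", None).to_numpy(dtype=object)
        p2 = df[f"{name}.p2"].replace("", None).to_numpy(dtype=object)
        genes[:, g, 0] = p1
        genes[:, g, 1] = p2
        for i in range(m):
            if p1[i] is not None and p2[i] is not None:
                obs[i, g] = OBS_DUPLICATED
            elif p1[i] is not None:
                obs[i, g] = OBS_SINGLE_P1
            elif p2[i] is not None:
                obs[i, g] = OBS_SINGLE_P2
            else:
                raise ValueError(
                    f"row {i + 2}: genome {name!r} has no gene in this pillar")
    flags = np.zeros((max(m - 1, 0), n), dtype=bool)
    for g, name in enumerate(genomes):
        col = df[f"{name}.double_break"].astype(int).to_numpy()
        if m > 1:
            flags[:, g] = col[:-1].astype(bool)
    return PillarSet(genomes=genomes, anchors=df["anchor"].to_numpy(dtype=object),
                     obs=obs, double_breaks=flags, genes=genes)


# ---------------------------------------------------------------- posteriors

def write_posteriors(posterior: PosteriorTable, path,
                     anchors: np.ndarray | None = None) -> None:
    """Pillar-by-assignment-vector posterior table (>= 12 significant
    digits) plus per-genome subgenome-1 marginals."""
    n = posterior.n_genomes
    V = posterior.vector_probs.shape[1]
    data = {"pillar": np.arange(posterior.m)}
    if anchors is not None:
        data["anchor"] = anchors
    for g, name in enumerate(posterior.genomes):
        data[f"marg.{name}"] = posterior.marginals[:, g]
    for v in range(V):
        bits = "".join(str(1 + ((v >> g) & 1)) for g in range(n))
        data[f"p.{bits}"] = posterior.vector_probs[:, v]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_posteriors(path) -> PosteriorTable:
    df = pd.read_csv(path, sep="\t")
    genomes = tuple(c[5:] for c in df.columns if c.startswith("marg."))
    vec_cols = [c for c in df.columns if c.startswith("p.")]
    if not genomes or not vec_cols:
        raise ValueError("posterior file missing marginal or vector columns")
    n = len(genomes)
    V = 1 << n
    probs = np.zeros((len(df), V))
    for c in vec_cols:
        bits = c[2:]
        v = sum((int(ch) - 1) << g for g, ch in enumerate(bits))
        probs[:, v] = df[c].to_numpy()
    marg = np.column_stack([df[f"marg.{g}"].to_numpy() for g in genomes])
    return PosteriorTable(genomes=genomes, vector_probs=probs, marginals=marg)


def write_fit_report(fit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2, default=float)
        fh.write("\n")


def read_fit_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
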