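"""Core containers: pillars, assignment vectors, junction model, posteriors.

A *pillar* is one ancestral (pre-WGD) locus, anchored by an outgroup gene,
with up to two slot genes per polyploid genome (the two homoeologous tracks,
p1 and p2).  Each genome's observation at a pillar is one of: both slots
occupied (the ohnolog pair survives), single copy in slot p1, or single copy
in slot p2.

An *assignment vector* v in {1,2}^n states, for each genome, which parental
subgenome its slot-1 track derives from.  Vectors are encoded as integers:
bit g of the index is 0 when v_g = 1 and 1 when v_g = 2, so the complement of
index ``i`` is ``i ^ (2**n - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: observation codes per genome per pillar
OBS_DUPLICATED = 0
OBS_SINGLE_P1 = 1
OBS_SINGLE_P2 = 2
OBS_LABELS = ("duplicated", "single_in_p1", "single_in_p2")

#: hard cap on genomes for the 2^n assignment-vector state space
MAX_GENOMES = 12


def n_vectors(n_genomes: int) -> int:
    if n_genomes > MAX_GENOMES:
        raise ValueError(
            f"{n_genomes} genomes would need 2^{n_genomes} assignment vectors; "
            f"the supported cap is {MAX_GENOMES} (4096 vectors). Analyze a "
            "subset of genomes or split the dataset.")
    return 1 << n_genomes

def vector_from_index(idx: int, n_genomes: int) -> np.ndarray:
    """Decode an assignment-vector index into an array over {1, 2}."""
    return np.array([1 + ((idx >> g) & 1) for g in range(n_genomes)], dtype=np.int8)


def index_from_vector(v) -> int:
    v = np.asarray(v)
    if not np.isin(v, (1, 2)).all():
        raise ValueError("assignment vector entries must be 1 or 2")
    return int(sum((int(x) - 1) << g for g, x in enumerate(v)))


def complement_index(idx: int, n_genomes: int) -> int:
    """The globally relabeled assignment (every subgenome label flipped)."""
    return idx ^ ((1 << n_genomes) - 1)


@dataclass
class PillarSet:
    """An ordered set of pillars across ``n`` polyploid genomes.

    obs : (m, n) int8 array of observation codes (OBS_*).
    double_breaks : (m-1, n) bool; entry (i, g) flags a double synteny break
        in genome g at the junction between pillar i and pillar i+1, which
        decorrelates subgenome assignment across that junction.
    genes : optional (m, n, 2) object array of slot gene identifiers (None
        for an empty slot); purely bookkeeping for the likelihood machinery.
    """

    genomes: tuple[str, ...]
    anchors: np.ndarray
    obs: np.ndarray
    double_breaks: np.ndarray
    genes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genomes = tuple(self.genomes)
        self.anchors = np.asarray(self.anchors, dtype=object)
        self.obs = np.asarray(self.obs, dtype=np.int8)
        m, n = self.obs.shape
        if len(self.genomes) != n:
            raise ValueError("obs width does not match number of genomes")
        if len(self.anchors) != m:
            raise ValueError("anchor count does not match pillar count")
        if not np.isin(self.obs, (0, 1, 2)).all():
            raise ValueError("invalid observation code")
        self.double_breaks = np.asarray(self.double_breaks, dtype=bool)
        if self.double_breaks.shape != (max(m - 1, 0), n):
            raise ValueError("double_breaks must have shape (m-1, n_genomes)")
        if self.genes is not None:
            self.genes = np.asarray(self.genes, dtype=object)
            if self.genes.shape != (m, n, 2):
                raise ValueError("genes must have shape (m, n_genomes, 2)")

    @property
    def m(self) -> int:
        return self.obs.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.obs.shape[1]

    def subset(self, start: int, stop: int) -> "PillarSet":
        """Contiguous run of pillars [start, stop); junction flags follow."""
        return PillarSet(
            genomes=self.genomes,
            anchors=self.anchors[start:stop],
            obs=self.obs[start:stop],
            double_breaks=self.double_breaks[start:max(stop - 1, start)],
            genes=None if self.genes is None else self.genes[start:stop],
        )

    def swap_tracks(self) -> "PillarSet":
        """Exchange the p1/p2 slots of every genome at every pillar."""
        obs = self.obs.copy()
        obs[self.obs == OBS_SINGLE_P1] = OBS_SINGLE_P2
        obs[self.obs == OBS_SINGLE_P2] = OBS_SINGLE_P1
        genes = None if self.genes is None else self.genes[:, :, ::-1].copy()
        return PillarSet(self.genomes, self.anchors, obs, self.double_breaks, genes)


@dataclass(frozen=True)
class JunctionModel:
    """Assignment-switching model between consecutive pillars.

    Each genome's assignment flips with probability theta at a junction,
    replaced by 1/2 wherever that genome has a double synteny break (the two
    sides of a double break carry no shared-order information).
    """

    theta: float
    double_breaks: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 0.5):
            raise ValueError(f"theta must lie in [0, 0.5], got {self.theta!r}")
        object.__setattr__(self, "double_breaks",
                           np.asarray(self.double_breaks, dtype=bool))

    @classmethod
    def for_pillars(cls, pillar_set: PillarSet, theta: float) -> "JunctionModel":
        return cls(theta=theta, double_breaks=pillar_set.double_breaks)

    def flip_probs(self, junction: int) -> np.ndarray:
        """Per-genome flip probability at a junction (theta or 0.5)."""
        probs = np.full(self.double_breaks.shape[1], self.theta)
        probs[self.double_breaks[junction]] = 0.5
        return probs


@dataclass
class PosteriorTable:
    """Posterior decoding of subgenome assignments.

    vector_probs : (m, 2^n) posterior over assignment-vector indices per pillar.
    marginals : (m, n) per-genome posterior probability that the slot-1 track
        derives from subgenome 1 (P(v_g = 1)).
    """

    genomes: tuple[str, ...]
    vector_probs: np.ndarray
    marginals: np.ndarray
    loglik: float = field(default=float("nan"))

    @property
    def m(self) -> int:
        return self.vector_probs.shape[0]

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)
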