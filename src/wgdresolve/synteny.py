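"""Building ancestral pillars from gene orders by simulated annealing.

Each polyploid genome is compared to a non-polyploid outgroup.  Every
outgroup gene anchors a candidate ancestral *pillar* with two slots (the two
homoeologous tracks created by the WGD); a pillar carries a set of candidate
homologs from the polyploid genome, at most two of which may be assigned to
its slots.  The quality of a joint choice of slot assignments and pillar
order is the synteny score: one point for every position whose slot gene is
a genomic neighbor of the next non-empty slot gene downstream (neighbor =
adjacent among analysis-set genes on the same chromosome; the scan does not
wrap and the last non-empty position contributes no term).

Simulated annealing maximizes the score by proposing order moves (pillar
swaps, segment relocations, segment reversals) and assignment moves (slot
reassignment/emptying, p1/p2 swaps), with Metropolis acceptance and
geometric cooling.  The score is maintained incrementally via local deltas
and periodically validated against a full recomputation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- genomes

class GenomeAnnotation:
    """Ordered gene lists per chromosome for one genome.

    The neighbor relation is adjacency within the current analysis set on
    the same chromosome (genes outside the analysis set are invisible).
    """

    def __init__(self, orders: dict[str, list[str]]):
        self.orders = {c: list(genes) for c, genes in orders.items()}
        self.position: dict[str, tuple[str, int]] = {}
        for chrom, genes in self.orders.items():
            for i, g in enumerate(genes):
                if g in self.position:
                    raise ValueError(f"duplicate gene id {g!r} in genome annotation")
                self.position[g] = (chrom, i)

    def __contains__(self, gene: str) -> bool:
        return gene in self.position

    def are_neighbors(self, a: str | None, b: str | None) -> bool:
        if a is None or b is None:
            return False
        pa = self.position.get(a)
        pb = self.position.get(b)
        if pa is None or pb is None:
            return False
        return pa[0] == pb[0] and abs(pa[1] - pb[1]) == 1

    def restrict(self, analysis_set) -> "GenomeAnnotation":
        """Annotation with only analysis-set genes (re-ranked positions)."""
        keep = set(analysis_set)
        return GenomeAnnotation({
            c: [g for g in genes if g in keep] for c, genes in self.orders.items()})


# ---------------------------------------------------------- homolog filter

def filter_homolog_pairs(records: pd.DataFrame, mode: str = "seed", *,
                         min_identity: float = 0.70,
                         min_len_ratio: float = 0.80,
                         min_seven_mers: int = 2,
                         max_evalue: float = 1e-8,
                         max_ka: float | None = 0.1) -> pd.DataFrame:
    """Accept candidate homolog pairs that pass the homology thresholds.

    seed mode requires >= ``min_seven_mers`` shared exact 7-residue matches;
    blast mode requires E-value <= ``max_evalue``.  Both require overall
    identity >= ``min_identity`` and shorter/longer length ratio >=
    ``min_len_ratio``.  When a ``ka`` column is present and ``max_ka`` is
    set, pairs above the nonsynonymous-divergence cutoff are dropped (this
    guards against homologs surviving from older, shared polyploidies).
    """
    if mode not in ("seed", "blast"):
        raise ValueError(f"mode must be 'seed' or 'blast', got {mode!r}")
    required = {"identity", "len_ratio"}
    required |= {"seven_mer_count"} if mode == "seed" else {"evalue"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing required columns for {mode} mode: "
                         f"{sorted(missing)}")
    ok = (records["identity"] >= min_identity) & (records["len_ratio"] >= min_len_ratio)
    if mode == "seed":
        ok &= records["seven_mer_count"] >= min_seven_mers
    else:
        ok &= records["evalue"] <= max_evalue
    if max_ka is not None and "ka" in records.columns:
        ok &= records["ka"].isna() | (records["ka"] <= max_ka)
    return records[ok].reset_index(drop=True)


def pair_stats(seq_a: str, seq_b: str) -> dict:
    """Seed-mode statistics for a protein pair computed from raw sequences.

    Shared 7-mers are counted as distinct exact 7-residue substrings present
    in both sequences; identity is global-alignment matches over the longer
    sequence length.
    """
    from Bio import Align

    def kmers(s):
        return {s[i:i + 7] for i in range(len(s) - 6)}

    shared = len(kmers(seq_a) & kmers(seq_b))
    lo, hi = sorted((len(seq_a), len(seq_b)))
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=0, open_gap_score=-1,
                                    extend_gap_score=-0.5)
    aln = aligner.align(seq_a, seq_b)[0]
    matches = sum(a == b for a, b in zip(str(aln[0]), str(aln[1])) if a != "-")
    return {"seven_mer_count": shared, "len_ratio": lo / hi,
            "identity": matches / hi}


# ------------------------------------------------------------ pillar types

@dataclass
class PillarCandidates:
    """Per-genome candidate pillars, in outgroup (anchor) order."""

    anchors: list[str]
    candidates: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.anchors) != len(self.candidates):
            raise ValueError("anchors and candidate sets differ in length")

    @property
    def m(self) -> int:
        return len(self.anchors)

    @classmethod
    def from_homologs(cls, homologs: pd.DataFrame, anchor_order: list[str]
                      ) -> "PillarCandidates":
        by_anchor: dict[str, list[str]] = {a: [] for a in anchor_order}
        for _, row in homologs.iterrows():
            if row["anchor"] in by_anchor:
                by_anchor[row["anchor"]].append(row["candidate"])
        return cls(anchors=list(anchor_order),
                   candidates=[tuple(by_anchor[a]) for a in anchor_order])


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the annealer."""

    t_initial: float = 3.0
    t_final: float = 0.01
    cooling: float = 0.995
    steps_per_temp: int = 20

    def __post_init__(self) -> None:
        if not (self.t_initial >= self.t_final > 0):
            raise ValueError("need t_initial >= t_final > 0")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")


DEFAULT_MOVES = {"swap": 0.4, "relocate": 0.2, "reverse": 0.1,
                 "reassign": 0.2, "swap_slots": 0.1}


@dataclass
class AnnealResult:
    order: list[int]
    assignments: list[list[str | None]]  # per pillar [p1, p2]
    score: int
    checkpoints: list[tuple[int, int]] = field(default_factory=list)
    n_proposed: int = 0
    n_accepted: int = 0


class AnnealState:
    """Mutable annealing state: a pillar order plus per-track slot genes.

    ``tracks`` is a list of (gene list per pillar, GenomeAnnotation); in the
    single-genome stage there are two tracks (slots p1/p2) over one genome,
    in the global-order stage two tracks per genome with assignments frozen.
    The synteny score is maintained incrementally: every move touches a
    bounded set of chain links, and only those terms are recomputed.
    """

    def __init__(self, track_assign: list[list], annotations: list,
                 order: list[int] | None = None):
        self.track_assign = [list(t) for t in track_assign]
        self.ann = list(annotations)
        self.m = len(self.track_assign[0])
        self.n_tracks = len(self.track_assign)
        self.order = list(range(self.m)) if order is None else list(order)
        if sorted(self.order) != list(range(self.m)):
            raise ValueError("order must be a permutation of pillar indices")
        # claim registry: a gene may occupy one slot in one pillar, per
        # genome (tracks of the same genome share an annotation object)
        self.used: dict[tuple[int, str], tuple[int, int]] = {}
        for t, genes in enumerate(self.track_assign):
            for p, g in enumerate(genes):
                if g is None:
                    continue
                key = (id(self.ann[t]), g)
                if key in self.used:
                    raise ValueError(f"gene {g!r} assigned twice")
                self.used[key] = (t, p)
        self.score = self.full_score()

    # ------------------------------------------------------------- scoring
    def _gene(self, t: int, pos: int):
        return self.track_assign[t][self.order[pos]]

    def full_score(self) -> int:
        s = 0
        for t in range(self.n_tracks):
            ann = self.ann[t]
            prev = None
            for pos in range(self.m):
                g = self._gene(t, pos)
                if g is None:
                    continue
                if prev is not None and ann.are_neighbors(prev, g):
                    s += 1
                prev = g
        return s

    def _prev_nonempty(self, t: int, pos: int):
        for p in range(pos - 1, -1, -1):
            if self._gene(t, p) is not None:
                return p
        return None

    def _next_nonempty(self, t: int, pos: int):
        for p in range(pos + 1, self.m):
            if self._gene(t, p) is not None:
                return p
        return None

    def _pairs_at_positions(self, t: int, positions) -> set[tuple[int, int]]:
        """Chain links (as position pairs) whose membership involves
        ``positions``: the links touching each non-empty position, or the
        link spanning each empty one."""
        pairs: set[tuple[int, int]] = set()
        for pos in positions:
            if self._gene(t, pos) is not None:
                pv = self._prev_nonempty(t, pos)
                nx = self._next_nonempty(t, pos)
                if pv is not None:
                    pairs.add((pv, pos))
                if nx is not None:
                    pairs.add((pos, nx))
            else:
                pv = self._prev_nonempty(t, pos)
                nx = self._next_nonempty(t, pos)
                if pv is not None and nx is not None:
                    pairs.add((pv, nx))
        return pairs

    def _pairs_at_cuts(self, t: int, cuts) -> set[tuple[int, int]]:
        """Chain links spanning each order gap in ``cuts`` (gap g sits
        between positions g and g+1)."""
        pairs: set[tuple[int, int]] = set()
        for g in cuts:
            if g < 0 or g + 1 >= self.m:
                continue
            left = g if self._gene(t, g) is not None else self._prev_nonempty(t, g)
            right = (g + 1 if self._gene(t, g + 1) is not None
                     else self._next_nonempty(t, g + 1))
            if left is not None and right is not None:
                pairs.add((left, right))
        return pairs

    def _sum_pairs(self, t: int, pairs) -> int:
        ann = self.ann[t]
        return sum(1 for a, b in pairs
                   if ann.are_neighbors(self._gene(t, a), self._gene(t, b)))

    def _local_positions(self, positions, tracks=None) -> int:
        tracks = range(self.n_tracks) if tracks is None else tracks
        return sum(self._sum_pairs(t, self._pairs_at_positions(t, positions))
                   for t in tracks)

    def _local_cuts(self, cuts) -> int:
        return sum(self._sum_pairs(t, self._pairs_at_cuts(t, cuts))
                   for t in range(self.n_tracks))

    # --------------------------------------------------------------- moves
    # each returns (delta, undo_callable) or None for an invalid proposal

    def move_swap(self, i: int, j: int):
        if i == j:
            return None
        old = self._local_positions((i, j))
        self.order[i], self.order[j] = self.order[j], self.order[i]
        delta = self._local_positions((i, j)) - old

        def undo():
            self.order[i], self.order[j] = self.order[j], self.order[i]

        return delta, undo

    def move_relocate(self, i: int, j: int, q: int):
        """Move segment [i..j] so that it precedes the element currently at
        position q (q < i or q > j + 1; q == m appends)."""
        if not (0 <= i <= j < self.m) or (i <= q <= j + 1):
            return None
        L = j - i + 1
        old = self._local_cuts((i - 1, j, q - 1))
        seg = self.order[i:j + 1]
        rest = self.order[:i] + self.order[j + 1:]
        d = q if q < i else q - L
        new_order = rest[:d] + seg + rest[d:]
        prev_order = self.order
        self.order = new_order
        # the removal seam: gap (i-1, i) when the segment moved right,
        # gap (j, j+1) when it moved left (old flanks become adjacent there)
        seam_left = i - 1 if q > j else j
        delta = self._local_cuts((d - 1, d + L - 1, seam_left)) - old

        def undo():
            self.order = prev_order

        return delta, undo

    def move_reverse(self, i: int, j: int):
        if not (0 <= i < j < self.m):
            return None
        old = self._local_cuts((i - 1, j))
        self.order[i:j + 1] = self.order[i:j + 1][::-1]
        delta = self._local_cuts((i - 1, j)) - old

        def undo():
            self.order[i:j + 1] = self.order[i:j + 1][::-1]

        return delta, undo

    def move_reassign(self, t: int, pillar: int, gene):
        """Set track t of ``pillar`` to ``gene`` (or None to empty it)."""
        current = self.track_assign[t][pillar]
        if gene == current:
            return None
        akey = id(self.ann[t])
        if gene is not None and (akey, gene) in self.used:
            return None  # double-claim proposals are rejected
        pos = self.order.index(pillar)
        old = self._local_positions((pos,), tracks=(t,))
        self.track_assign[t][pillar] = gene
        if current is not None:
            del self.used[(akey, current)]
        if gene is not None:
            self.used[(akey, gene)] = (t, pillar)
        delta = self._local_positions((pos,), tracks=(t,)) - old

        def undo():
            self.track_assign[t][pillar] = current
            if gene is not None:
                del self.used[(akey, gene)]
            if current is not None:
                self.used[(akey, current)] = (t, pillar)

        return delta, undo

    def move_swap_slots(self, pillar: int):
        if self.n_tracks != 2:
            return None
        a = self.track_assign[0][pillar]
        b = self.track_assign[1][pillar]
        if a is None and b is None:
            return None
        pos = self.order.index(pillar)
        akey = id(self.ann[0])
        old = self._local_positions((pos,))
        self.track_assign[0][pillar] = b
        self.track_assign[1][pillar] = a
        if a is not None:
            self.used[(akey, a)] = (1, pillar)
        if b is not None:
            self.used[(akey, b)] = (0, pillar)
        delta = self._local_positions((pos,)) - old

        def undo():
            self.track_assign[0][pillar] = a
            self.track_assign[1][pillar] = b
            if a is not None:
                self.used[(akey, a)] = (0, pillar)
            if b is not None:
                self.used[(akey, b)] = (1, pillar)

        return delta, undo


# ------------------------------------------------------------------ scoring

def synteny_score(assignments: list, order: list[int],
                  annotation: GenomeAnnotation) -> int:
    """Synteny score of one genome's slot assignments under a pillar order.

    For each slot chain (p1 and p2), one point per position whose gene is a
    genomic neighbor of the next non-empty gene downstream.
    """
    score = 0
    for k in (0, 1):
        prev = None
        for p in order:
            g = assignments[p][k]
            if g is None:
                continue
            if prev is not None and annotation.are_neighbors(prev, g):
                score += 1
            prev = g
    return score


def _greedy_assignments(candidates: PillarCandidates) -> list[list]:
    """Deterministic starting assignment: first two unclaimed candidates."""
    used: set[str] = set()
    out = []
    for cand in candidates.candidates:
        slots: list = [None, None]
        k = 0
        for g in cand:
            if g not in used and k < 2:
                slots[k] = g
                used.add(g)
                k += 1
        out.append(slots)
    return out


def anneal(candidates: PillarCandidates, annotation: GenomeAnnotation, *,
           seed: int, order: list[int] | None = None,
           assignments: list | None = None,
           schedule: AnnealSchedule | None = None,
           moves: dict[str, float] | None = None,
           order_only: bool = False,
           validate_every: int = 2000) -> AnnealResult:
    """Jointly optimize slot assignments and pillar order for one genome.

    Metropolis acceptance on the score change with geometric cooling; the
    best configuration ever visited is returned.  Reproducible for a given
    seed.  Every ``validate_every`` proposals the incrementally maintained
    score is checked against a full recomputation (exact equality).
    """
    if candidates.m == 0:
        raise ValueError("empty candidate set")
    schedule = schedule or AnnealSchedule()
    moves = dict(moves or DEFAULT_MOVES)
    if order_only:
        for name in ("reassign", "swap_slots"):
            moves.pop(name, None)
    if candidates.m == 1:
        moves = {k: v for k, v in moves.items() if k in ("reassign", "swap_slots")}
    assignments = assignments if assignments is not None else _greedy_assignments(candidates)
    state = AnnealState([[s[0] for s in assignments], [s[1] for s in assignments]],
                        [annotation, annotation], order=order)
    return _run_anneal(state, candidates, schedule, moves, seed, validate_every)


def _run_anneal(state: AnnealState, candidates, schedule, moves, seed,
                validate_every) -> AnnealResult:
    rng = np.random.default_rng(seed)
    names = sorted(moves)
    weights = np.array([moves[n] for n in names], dtype=float)
    if not names or weights.sum() <= 0:
        raise ValueError("no applicable moves")
    weights /= weights.sum()
    m = state.m
    best_score = state.score
    best = (list(state.order), [list(t) for t in state.track_assign])
    n_prop = n_acc = 0
    checkpoints: list[tuple[int, int]] = []
    t = schedule.t_initial
    while t >= schedule.t_final:
        for _ in range(schedule.steps_per_temp):
            n_prop += 1
            name = names[rng.choice(len(names), p=weights)]
            res = _propose(state, name, rng, candidates)
            if res is None:
                continue
            delta, undo = res
            if delta >= 0 or rng.random() < np.exp(delta / t):
                state.score += delta
                n_acc += 1
                if state.score > best_score:
                    best_score = state.score
                    best = (list(state.order),
                            [list(tr) for tr in state.track_assign])
            else:
                undo()
            if n_prop % validate_every == 0:
                full = state.full_score()
                checkpoints.append((state.score, full))
                if full != state.score:
                    raise RuntimeError(
                        f"incremental score {state.score} != full recomputation {full}")
        t *= schedule.cooling
    checkpoints.append((best_score, _score_config(best, state)))
    order, tracks = best
    assignments = [[tracks[0][p], tracks[1][p]] if len(tracks) == 2 else None
                   for p in range(m)]
    return AnnealResult(order=order, assignments=assignments, score=best_score,
                        checkpoints=checkpoints, n_proposed=n_prop,
                        n_accepted=n_acc)


def _score_config(config, state: AnnealState) -> int:
    order, tracks = config
    probe = AnnealState(tracks, state.ann, order=order)
    return probe.score


def _propose(state: AnnealState, name: str, rng, candidates):
    m = state.m
    if name == "swap":
        i, j = rng.integers(0, m, size=2)
        return state.move_swap(int(i), int(j))
    if name == "relocate":
        i = int(rng.integers(0, m))
        j = min(m - 1, i + int(rng.integers(0, min(5, m))))
        q = int(rng.integers(0, m + 1))
        return state.move_relocate(i, j, q)
    if name == "reverse":
        i = int(rng.integers(0, m))
        j = min(m - 1, i + 1 + int(rng.integers(0, min(6, m))))
        return state.move_reverse(i, j)
    if name == "reassign":
        p = int(rng.integers(0, m))
        options = list(candidates.candidates[p]) + [None]
        gene = options[int(rng.integers(0, len(options)))]
        t = int(rng.integers(0, 2))
        return state.move_reassign(t, p, gene)
    if name == "swap_slots":
        return state.move_swap_slots(int(rng.integers(0, m)))
    raise ValueError(f"unknown move {name!r}")


def exhaustive_best(candidates: PillarCandidates,
                    annotation: GenomeAnnotation) -> int:
    """Globally optimal synteny score by enumerating all orders and
    assignments.  Only feasible for toy instances (<= ~7 pillars, <= 2
    candidates per pillar); serves as the ground-truth optimum for the
    annealer."""
    m = candidates.m
    per_pillar_options = []
    for cand in candidates.candidates:
        opts = [(None, None)]
        for g in cand:
            opts += [(g, None), (None, g)]
        for g, h in itertools.permutations(cand, 2):
            opts.append((g, h))
        per_pillar_options.append(opts)
    best = 0
    for assign in itertools.product(*per_pillar_options):
        genes = [g for slots in assign for g in slots if g is not None]
        if len(genes) != len(set(genes)):
            continue  # a homolog may fill only one slot globally
        for order in itertools.permutations(range(m)):
            s = synteny_score(assign, list(order), annotation)
            if s > best:
                best = s
    return best


# ------------------------------------------------------- multi-genome stage

@dataclass
class MergedPillars:
    """Cross-genome pillar set anchored by outgroup genes.

    slots : (m, n_genomes, 2) object array of gene ids (None = empty slot).
    """

    anchors: list[str]
    genomes: list[str]
    slots: np.ndarray
    annotations: dict[str, GenomeAnnotation]

    def __post_init__(self) -> None:
        self.slots = np.asarray(self.slots, dtype=object)
        if self.slots.shape != (len(self.anchors), len(self.genomes), 2):
            raise ValueError("slots must have shape (m, n_genomes, 2)")

    @property
    def m(self) -> int:
        return len(self.anchors)

    def reorder(self, order: list[int]) -> "MergedPillars":
        return MergedPillars(anchors=[self.anchors[p] for p in order],
                             genomes=self.genomes,
                             slots=self.slots[list(order)],
                             annotations=self.annotations)


@dataclass
class BreakReport:
    """Synteny-break flags in pillar-order coordinates."""

    breaks: np.ndarray       # (m, n, 2) bool
    double_breaks: np.ndarray  # (m, n) bool
    n_breaks: int
    n_double_breaks: int

    def per_genome(self, genomes: list[str]) -> pd.DataFrame:
        return pd.DataFrame({
            "genome": genomes,
            "n_breaks": self.breaks.sum(axis=(0, 2)),
            "n_double_breaks": self.double_breaks.sum(axis=0),
        })


def detect_breaks(merged: MergedPillars, order: list[int] | None = None
                  ) -> BreakReport:
    """Flag synteny breaks: position i carries a break for (genome, slot)
    when its slot gene and the next non-empty slot gene downstream are not
    genomic neighbors; a double break is a break in both slots at once."""
    m = merged.m
    order = list(range(m)) if order is None else order
    n = len(merged.genomes)
    breaks = np.zeros((m, n, 2), dtype=bool)
    for gi, genome in enumerate(merged.genomes):
        ann = merged.annotations[genome]
        for k in (0, 1):
            chain = [(r, merged.slots[p, gi, k]) for r, p in enumerate(order)
                     if merged.slots[p, gi, k] is not None]
            for (r1, g1), (_, g2) in zip(chain, chain[1:]):
                if not ann.are_neighbors(g1, g2):
                    breaks[r1, gi, k] = True
    double = breaks[:, :, 0] & breaks[:, :, 1]
    return BreakReport(breaks=breaks, double_breaks=double,
                       n_breaks=int(breaks.sum()),
                       n_double_breaks=int(double.sum()))


def _supported_genes(candidates: PillarCandidates, result: AnnealResult,
                     annotation: GenomeAnnotation) -> set[str]:
    """Genes with synteny support: neighbor-linked to the previous or next
    non-empty gene of their slot chain in the annealed configuration."""
    supported: set[str] = set()
    for k in (0, 1):
        chain = [result.assignments[p][k] for p in result.order
                 if result.assignments[p][k] is not None]
        for i, g in enumerate(chain):
            if (i > 0 and annotation.are_neighbors(chain[i - 1], g)) or \
               (i + 1 < len(chain) and annotation.are_neighbors(g, chain[i + 1])):
                supported.add(g)
    return supported


def merge_pillars(per_genome: dict[str, tuple[PillarCandidates, AnnealResult]],
                  annotations: dict[str, GenomeAnnotation]) -> MergedPillars:
    """Merge per-genome pillar inferences into one cross-genome set.

    Within each genome, slot genes without synteny support are dropped;
    a merged pillar is retained only when every genome still contributes at
    least one gene.  Pillars are indexed by their shared outgroup anchors.
    """
    genomes = sorted(per_genome)
    anchor_lists = [tuple(per_genome[g][0].anchors) for g in genomes]
    if len(set(anchor_lists)) != 1:
        raise ValueError("inconsistent anchors across per-genome pillar sets")
    anchors = list(anchor_lists[0])
    m = len(anchors)
    slots = np.empty((m, len(genomes), 2), dtype=object)
    for gi, genome in enumerate(genomes):
        candidates, result = per_genome[genome]
        keep = _supported_genes(candidates, result, annotations[genome])
        for p in range(m):
            for k in (0, 1):
                g = result.assignments[p][k]
                slots[p, gi, k] = g if (g is not None and g in keep) else None
    occupied = np.array([[any(slots[p, gi, k] is not None for k in (0, 1))
                          for gi in range(len(genomes))] for p in range(m)])
    rows = [p for p in range(m) if occupied[p].all()]
    return MergedPillars(anchors=[anchors[p] for p in rows],
                         genomes=genomes, slots=slots[rows],
                         annotations={g: annotations[g] for g in genomes})


def optimize_global_order(merged: MergedPillars, *, seed: int,
                          schedule: AnnealSchedule | None = None,
                          initial_order: list[int] | None = None,
                          validate_every: int = 2000) -> AnnealResult:
    """Anneal the shared ancestral pillar order with assignments frozen.

    The optimality criterion is the total number of neighbor relationships
    across all genomes and both slots.  The returned result carries the
    best-ever order; the per-pillar assignments are unchanged.
    """
    tracks, anns = [], []
    for gi, genome in enumerate(merged.genomes):
        for k in (0, 1):
            tracks.append([merged.slots[p, gi, k] for p in range(merged.m)])
            anns.append(merged.annotations[genome])
    state = AnnealState(tracks, anns, order=initial_order)
    moves = {k: v for k, v in DEFAULT_MOVES.items()
             if k in ("swap", "relocate", "reverse")}
    dummy = PillarCandidates(anchors=list(merged.anchors),
                             candidates=[()] * merged.m)
    result = _run_anneal(state, dummy, schedule or AnnealSchedule(), moves,
                         seed, validate_every)
    result.assignments = [[merged.slots[p, gi, k] for gi in range(len(merged.genomes))
                           for k in (0, 1)] for p in range(merged.m)]
    return result


def global_order_score(merged: MergedPillars, order: list[int]) -> int:
    """Total neighbor count across genomes and slots for a pillar order."""
    total = 0
    for gi, genome in enumerate(merged.genomes):
        assignments = [(merged.slots[p, gi, 0], merged.slots[p, gi, 1])
                       for p in range(merged.m)]
        total += synteny_score(assignments, order, merged.annotations[genome])
    return total


def high_synteny_subset(merged: MergedPillars, order: list[int] | None = None
                        ) -> MergedPillars:
    """Pillars with full syntenic support in at least one direction.

    A pillar is kept when, in every genome, all of its occupied slots are
    neighbor-linked toward the same side (all toward the predecessor or all
    toward the successor non-empty position of their chains).
    """
    m = merged.m
    if m == 0:
        return merged
    order = list(range(m)) if order is None else order
    n = len(merged.genomes)
    # linked[r, gi, k, d]: slot chain link exists toward d (0=pred, 1=succ)
    linked = np.zeros((m, n, 2, 2), dtype=bool)
    occupied = np.zeros((m, n, 2), dtype=bool)
    for gi, genome in enumerate(merged.genomes):
        ann = merged.annotations[genome]
        for k in (0, 1):
            chain = [(r, merged.slots[p, gi, k]) for r, p in enumerate(order)
                     if merged.slots[p, gi, k] is not None]
            for i, (r, g) in enumerate(chain):
                occupied[r, gi, k] = True
                if i > 0 and ann.are_neighbors(chain[i - 1][1], g):
                    linked[r, gi, k, 0] = True
                if i + 1 < len(chain) and ann.are_neighbors(g, chain[i + 1][1]):
                    linked[r, gi, k, 1] = True
    keep_rows = []
    for r in range(m):
        ok = True
        for gi in range(n):
            occ = occupied[r, gi]
            if not occ.any():
                ok = False
                break
            directional = [(linked[r, gi, :, d] | ~occ).all() for d in (0, 1)]
            if not any(directional):
                ok = False
                break
        if ok:
            keep_rows.append(order[r])
    idx = {p: i for i, p in enumerate(keep_rows)}
    return MergedPillars(anchors=[merged.anchors[p] for p in keep_rows],
                         genomes=merged.genomes, slots=merged.slots[keep_rows],
                         annotations=merged.annotations)


def pillar_set_from_merged(merged: MergedPillars, order: list[int] | None = None):
    """Convert a merged pillar set (plus an order) into the observation/break
    representation consumed by the likelihood machinery."""
    from .pillars import (OBS_DUPLICATED, OBS_SINGLE_P1, OBS_SINGLE_P2,
                          PillarSet)
    m = merged.m
    order = list(range(m)) if order is None else order
    n = len(merged.genomes)
    report = detect_breaks(merged, order)
    obs = np.empty((m, n), dtype=np.int8)
    genes = np.empty((m, n, 2), dtype=object)
    for r, p in enumerate(order):
        for gi in range(n):
            p1, p2 = merged.slots[p, gi]
            genes[r, gi, 0] = p1
            genes[r, gi, 1] = p2
            if p1 is not None and p2 is not None:
                obs[r, gi] = OBS_DUPLICATED
            elif p1 is not None:
                obs[r, gi] = OBS_SINGLE_P1
            elif p2 is not None:
                obs[r, gi] = OBS_SINGLE_P2
            else:
                raise ValueError(
                    f"pillar {merged.anchors[p]!r} has no gene for genome "
                    f"{merged.genomes[gi]!r}; merge first")
    return PillarSet(genomes=tuple(merged.genomes),
                     anchors=np.array([merged.anchors[p] for p in order],
                                      dtype=object),
                     obs=obs, double_breaks=report.double_breaks[:-1],
                     genes=genes)
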