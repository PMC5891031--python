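# Methods

## The loss model

Each ancestral locus of a paleopolyploid clade is modeled as a continuous-
time Markov chain on {U, F, S1, S2} running along a rooted species tree
whose root is the WGD event itself (state U with probability one).  The
only transient state is U, with generator row

    Q[U] = ( -(1+ε+γ),  γ,  1,  ε )        (order U, F, S1, S2)

F, S1 and S2 are absorbing: a fixed duplicate never reverts, and a lost
copy never returns.  Two unit conventions matter:

- **Branch lengths are α·t.**  The base loss rate α multiplies time
  everywhere, so it is absorbed into the branch lengths by fixing
  rate(U→S1) = 1.  A branch of length 1 is one expected subgenome-1-loss
  time.  An alternative convention scales the total U outflow to 1; it
  would only rescale reported branch lengths by (1+ε+γ), leaving γ, ε, θ
  and all likelihood ratios unchanged.
- **ε multiplies the loss rate into S2.**  Consequently
  P(U→S2)/P(U→S1) = ε on any branch, so the maximum-likelihood ε is
  directly comparable to the observed ratio of single-copy genes retained
  from the more vs the less fractionated subgenome.

Transition probabilities are available in closed form (the absorbed mass
(1−e^{−(1+ε+γ)b}) splits proportionally to the rates); the implementation
is validated against a generic matrix exponential and against the
Chapman–Kolmogorov identity.

## Emissions, the assignment HMM, and decoding

A pillar observation per genome is one of {duplicated, single in slot p1,
single in slot p2}.  The latent assignment v_g ∈ {1,2} says which parental
subgenome genome g's slot-1 track derives from, so a single survivor in p1
is an S1 loss if v_g = 1 and an S2 loss if v_g = 2 (slot p2 mirrored);
duplicated observations are compatible with U and F.  Pruning shares
partial likelihoods across assignment vectors: a subtree spanning k genomes
distinguishes only 2^k local assignment patterns, so filling the full
(m × 2^n) emission table costs O(m · Σ_nodes 2^{k(node)}) rather than
O(m · 2^n · nodes).

Along the ancestral order, assignments form a hidden Markov chain over the
2^n vectors with uniform initial distribution (no positional information
precedes the first pillar).  The junction kernel factorizes per genome:
genome g keeps its assignment with probability 1−θ_g, where θ_g = θ
globally and θ_g = 1/2 at junctions where that genome has a double synteny
break.  The per-genome factorization makes the double-break rule exact per
genome, and gives whole-vector stay probability (1−θ)^n ≈ 1−nθ for the
small θ regime the model targets (θ well below 0.01 on real-scale data).
An alternative reading — a single shared switch event for the whole vector
— differs only at O(θ²) and is not implemented.

Forward/backward recursions are scaled per position (log scale factors
accumulated) and jit-compiled; one junction update costs O(n·2^n).  The
hidden-state count caps at n = 12 genomes (4096 vectors); larger inputs are
rejected with guidance to subset.  Posterior decoding (forward–backward)
yields per-pillar vector posteriors and per-genome marginals; Viterbi
decoding is deliberately not provided, as every downstream quantity uses
marginal posteriors.

Expected per-branch loss counts exploit absorbency: a loss-to-S1 happened
on a branch iff the parent node is in U and the child in S1, so the
expected count is the posterior-weighted sum over pillars and vectors of
the joint parent/child probability, computed by an inside–outside pass and
cross-validated against realized event counts on simulations.

### A symmetry worth knowing

Complementing every assignment vector while swapping the data's slot tracks
is an exact symmetry of the mixture likelihood for *any* ε, because the sum
over all 2^n vectors is flip-invariant.  At ε = 1 the symmetry additionally
holds pointwise: each vector's likelihood equals its complement's, the
posteriors are relabeling-symmetric and subgenomes are unidentifiable.
With ε < 1 the pointwise symmetry breaks on asymmetric data and subgenome
labels become estimable.  A second consequence: with branch lengths and γ
free, the profile log-likelihood is an even function of log ε around ε = 1
(relabeling maps ε → 1/ε up to a time rescaling absorbed by the free branch
lengths).  The score for ε at the null ε = 1 is therefore identically zero,
and the WGD-f vs WGD-bf likelihood-ratio statistic has an atom at 0 —
rejection at nominal level α runs near α/2.  Reported p-values use the
plain χ²₁ tail, as is standard practice for this test; they are
conservative, and the calibration study in the acceptance suite measures
the realized size.

## Fitting

All free parameters (per-branch lengths, γ, ε or ε_early/ε_late, θ) are
maximized jointly with L-BFGS-B under box bounds
(b ∈ [10⁻⁴, 25], γ ∈ [0, 50], ε ∈ [0, 1], θ ∈ [10⁻⁵, 0.5]).  Raw bounded
parameters are used instead of log/logit transforms so the LRT null values
ε = 1 and γ = 0 are attainable exactly.  Convergence uses the optimizer's
relative-reduction criterion at ftol = 10⁻¹¹ (tighter than 10⁻⁶ lnL units
at the likelihood magnitudes involved); non-convergence is flagged on the
result, never raised.  Warm starts (e.g. initializing WGD-bf from the
WGD-f optimum) and seeded random multi-starts are supported; on simulated
data of 2000 pillars, re-fits from perturbed starts agree to within 0.01
lnL units.  θ is re-estimated per family rather than fixed across model
comparisons.  The "early" branch class for WGD-btf defaults to the
branches incident to the WGD root — the stem branch when the tree has one.

Rooted topology sweeps enumerate all (2k−3)!! topologies for k ≤ 5 taxa
(15 for four), fit each and rank by lnL, breaking ties by free-parameter
count then lexicographic newick.  Per-block ε estimates re-fit ε by profile
likelihood within each block (≥ 100 pillars by default) with all other
parameters at the global MLE.

## The synteny pipeline

Homolog candidates are filtered by: ≥ 2 shared exact 7-residue matches
(seed mode) or E ≤ 10⁻⁸ (BLAST mode), shorter/longer length ratio ≥ 0.8,
overall identity ≥ 70%, and optionally a nonsynonymous-divergence cutoff
(Ka ≤ 0.1 by default, relaxable per genome) to avoid pairs surviving from
older polyploidies shared with the outgroup.  Seed-mode statistics can be
computed from raw protein sequences (shared distinct 7-mers; identity =
global-alignment matches over the longer length).

The synteny score of a configuration counts, per slot chain, positions
whose gene is a genomic neighbor of the next non-empty gene downstream;
*neighbor* means adjacent among analysis-set genes on the same chromosome
(undirected), the scan does not wrap, and the last non-empty position
contributes no term.  Simulated annealing maximizes the score with move mix
40% pillar swaps, 20% segment relocations, 10% segment reversals, 20% slot
reassignments (including emptying), 10% p1/p2 swaps — order-only stages
renormalize over the first three — under Metropolis acceptance with
geometric cooling (T ← 0.995·T from 3.0 down to 0.01, 20 proposals per
temperature by default; tuned on the test-suite instance sizes).  A gene
may occupy one slot of one pillar globally; double-claiming proposals are
rejected.  The score is maintained incrementally — each move touches a
bounded set of chain links, identified via the positions or order-cuts the
move affects — and checked against a full recomputation every 2000
proposals (exact integer equality, enforced at runtime).  The best-ever
configuration is returned, updated on strict improvement only, so a
zero-temperature schedule started at an optimum returns it unchanged.

Merging keeps, per genome, only slot genes with synteny support (neighbor-
linked to the previous or next gene of their slot chain in the annealed
configuration) and then retains pillars where every genome still
contributes at least one gene.  The global ancestral order is re-annealed
with assignments frozen, maximizing total neighbor links across all genomes
and slots.  The high-synteny subset keeps pillars where, per genome, all
occupied slots link toward a common side (predecessor or successor);
links are required for occupied slots only.  Double breaks (both slots
break after a position) map to the HMM's junction flags.

## The simulator

The generator is the model read forwards, with ground truth retained at
every level (internal node states, per-branch loss events, assignment
chains, break placements).  Default study conditions are plant-like:
caterpillar trees with stem 0.5 and tip/internal branches 0.15–0.35 (α·t),
γ = 0.17, ε = 0.65, θ = 0.005 (inside the 0.0004–0.008 range typical of
real fits), and double breaks planted per genome per junction at rate 0.02
(matching the per-genome-junction double-break frequency of optimized
real-scale pillar sets).  Validation problem sizes are chosen so each stage
is tested where it is statistically meaningful: 5000 pillars × 6 genomes
for WGD-bf recovery, 4000 for the early/late bias split, 400 × 3 genomes ×
200 replicates for LRT calibration, 3000 × 4 genomes for topology recovery.

What the simulator does *not* emulate: real rearrangement processes
(breaks are planted as independent Bernoulli junction events rather than
arising from inversions/translocations), assembly fragmentation, missing or
mis-annotated genes, paralogs from small-scale duplication contaminating
the homolog candidate sets, and any sequence-level evolution.  Passing
tests therefore demonstrate correctness and statistical behavior of the
inference machinery under the model's own assumptions, not robustness to
the full error structure of real genome assemblies.  The pipeline round
trip uses loss-free, rearrangement-free genomes because only there is the
exact analytic optimum (score 2(m−1)·n) known; order recovery is asserted
up to global reversal, which is score-equivalent and unidentifiable.

## The network test

Single-copy genes get a subgenome label (argmax of the posterior marginal)
and a confidence (its probability).  The test statistic is the number of
interaction edges whose endpoints carry different labels; the null shuffles
labels across genes (multiset preserved, gene-level exchangeability), with
the add-one estimator p = (1+#{null ≤ obs})/(1+N) to avoid zero p-values.
An optional pillar-level permutation (shuffling labels by pillar, which
preserves within-pillar linkage) is available via the gene table's pillar
column; gene-level is the default.  Degree is not preserved under either
scheme.  The confidence sweep repeats the test above increasing confidence
thresholds and reports the crossing/same-subgenome edge-count ratio;
thresholds that leave fewer than two labeled genes or no testable edges
produce empty (NaN) rows.

## Numerical choices and degenerate inputs

- Emission rows are scaled to max 1 with log offsets; a pillar whose
  likelihood is zero for every vector (impossible data under the
  parameters) makes the total log-likelihood −∞, which the fitter treats
  as a rejected point (objective 10¹²).
- Oracle equivalences are asserted at 10⁻⁹ (HMM vs enumeration) and 10⁻¹⁰
  (closed form vs expm); forward/backward agreement is checked via chain
  reversal, exact because the junction kernel is symmetric.
- Branch lengths of exactly 0 are legal (identity transition); the lower
  fitting bound 10⁻⁴ keeps the optimizer off the exact boundary.
- Expected-count ratios report NaN when the denominator E[→S1] is zero.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical (config, seed) reproduce every artifact bit-exactly.

## Known limitations

- The convergent-loss model class (duplicated states committed to losing a
  specific copy) is out of scope; data generated under such dynamics will
  inflate ε̂ rather than be detected separately.
- The LRT for ε at its boundary is conservative (see the symmetry note);
  the package reports plain χ² p-values rather than mixture corrections.
- The annealer's schedule is tuned for the instance sizes exercised here;
  genome-scale runs (thousands of pillars) need longer schedules, supplied
  via `AnnealSchedule`.
- Subgenome labels are exchangeable across unlinked regions when ε is near
  1: blocks separated by all-genome double breaks then carry independent,
  arbitrary label orientations.
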