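# Methods

## Problem

A bicluster of an n×m expression matrix D = {d_ij} is a pair
(g ⊂ genes, c ⊂ conditions) whose submatrix is coherent.  Coherence is
measured by the Cheng–Church mean squared residue

    MSR(g, c) = mean over (i,j) in g×c of (d_ij − d_iJ − d_Ij + d_IJ)²,

where d_iJ, d_Ij, d_IJ are the row, column and overall means of the
submatrix.  MSR is 0 exactly when the submatrix is additive
(d_ij = μ + α_i + β_j), and a bicluster is a δ-bicluster when
MSR ≤ δ.  The search targets δ-biclusters of maximum volume
(|g|·|c|) with high row variance (mean of (d_ij − d_iJ)², which
excludes flat, uninformative submatrices).  The three goals conflict,
so the problem is posed as three-objective minimization of

    f = (MSR, −volume, −row variance),

with constrained dominance: a δ-feasible solution dominates any
infeasible one (this is also implied componentwise: an infeasible
solution has strictly larger MSR than every feasible one), and within
a class ordinary Pareto dominance applies.  Reported results are the
feasible members of the final archive, largest volume first, ties by
lower MSR.

## Encoding and operators

A bicluster is a binary string of length n+m (gene bits then condition
bits, `#` separator in text form).  Mutation flips k distinct bits:
near mutations draw k from {1..k_near}, far mutations from
{k_near+1..k_far}, with k_near ≈ 1% and k_far ≈ 5% of n+m by default.
A repair step turns random bits back on if a segment falls below the
minimum bicluster size (2×2 by default; 1×k biclusters have MSR 0
trivially and degenerate row variance, so they are excluded outright).

## The ε-archive

Pareto-optimal solutions are preserved in an ε-dominance box archive.
Raw objectives span four to five decades (the MSR of a random
submatrix of 0–600-scale data is ~3·10⁴; a coherent bicluster's is
<300), so box coordinates are computed on log-compressed objectives
(log1p of each magnitude, signs arranged to preserve minimization
order) min–max normalized to [0, 1]; box index = floor(f_i/ε_i) with
ε = 0.02 per objective by default.  The normalization bounds track the
population with hysteresis: they are padded by 5% and rebuilt only
when escaped, because every rebuild can merge boxes and shed members.
One solution is kept per box, no kept box may be dominated by another,
and a same-box collision keeps the solution closer (Euclidean) to the
box's lower corner, ties to the incumbent — the standard ε-Pareto-set
scheme, which bounds the archive while enforcing spread.  The archive
holds the current box-front of *both* feasibility classes: the
infeasible strata are the MSR-descent frontier from which feasible
biclusters are eventually carved, and discarding them (e.g. keeping
only feasible members) measurably destroys the search's ability to
localize more than one coherent submatrix.  A capacity (default 200)
is enforced by crowding-distance truncation, dropping infeasible
members first.  Note that ε-archives guarantee convergence to an
ε-approximate Pareto set, not monotone hypervolume: the corner-distance
replacement can swap in a solution that does not dominate the one it
evicts, so the archive's hypervolume occasionally dips (empirically
~95% of generation-to-generation steps are non-decreasing).

## Sigma-method guides

Each archive member j gets a direction-like value
σ_j = (f1²−f2², f2²−f3², f3²−f1²) / (f1²+f2²+f3²) computed on its
normalized objectives (scale-invariant; the all-zero vector maps to
σ = 0).  An antibody's best local guide is the archive member whose σ
lies at minimum Euclidean distance from its own — the archive solution
pulling in the most similar trade-off direction.  Ties go to the
lowest archive index, so guide selection is deterministic given
archive order.

## The immune loop

Each generation:

1. every population member is offered to the archive;
2. **clonal expansion** — the candidate set is the population's
   (unconstrained) Pareto front united with the archive members; the
   archive's ε-boxes act as niches, so several coherent submatrices
   are pursued in parallel.  ns = floor(r1·|candidates|) of them are
   drawn without replacement (r1 ~ U[0,1]); each spawns c clones
   (c = c_max for δ-feasible parents — affinity-proportional
   expansion — else uniform on {c_min..c_max}), each clone a near
   mutation with probability p_near = 0.9;
3. **environmental truncation** — if the population exceeds N_max,
   duplicates are merged and a two-class selection keeps the feasible
   class by (Pareto rank, volume) up to ~70% of the ceiling and fills
   the rest with infeasible antibodies by (rank, crowding).  Volume
   rather than crowding breaks feasible ties because volume growth
   relies on retaining several near-frontier members of the same
   submatrix — exactly the dense cluster crowding would thin;
4. **population decrease** — round(S·|P|) antibodies are removed
   (S = 0.02), chosen by weighted draw among the ~20% whose σ value is
   farthest from their best local guide: stragglers not tracking any
   archive direction.  The population never drops below N_min.

The initial archive comes from a compact NSGA-II (30 individuals, 10
generations; binary tournament, uniform crossover at 0.9, per-bit flip
at 1/(n+m)) on random biclusters (gene bits on with probability 10/n,
condition bits with probability 0.5).  The initial population is 4/5
gene-pair probes (two random genes across ~half the conditions) and
1/5 minimal 2×2 biclusters: a probe whose genes are co-expressed is a
handful of condition deletions away from a δ-bicluster, which is what
lets the clonal search localize coherent structure in an otherwise
unstructured matrix.

Termination is a fixed generation count; there is no convergence-based
early stopping.

## Parameters

| parameter | default | meaning |
|---|---|---|
| δ | 300 (yeast-scale), 1200 (human-scale) | MSR feasibility threshold, squared expression units |
| ε | 0.02 ×3 | box width on [0,1] log-normalized objectives |
| generations | 100 | fixed iteration count |
| N_min / N_max / initial | 20 / 300 / 50 | population size bounds |
| S | 0.02 | fraction pruned per generation (≤ 0.2) |
| c_min / c_max | 1 / 10 | clone-count bounds per candidate |
| p_near | 0.9 | probability of a near mutation |
| k_near / k_far | 1% / 5% of n+m | flip-count bounds |
| capacity | 200 | archive size bound |
| top_k | 100 | number of reported biclusters |
| impute bounds | [0, 800] / [−800, 800] | uniform imputation range (yeast- / human-like) |

c_max = 10 was chosen so the volume-growth frontier receives on the
order of one expected improving clone per generation at desk scale;
all other defaults follow the conventions above.

## Synthetic data

The generator emulates the two classic compendia: uniform background
on the data range (0–600 yeast-like, −750–650 human-like), planted
constant or additive (μ + α_i + β_j) submatrices with Gaussian cell
noise, and a configurable fraction of missing entries (masked, then
imputed by uniform draws — [0, 800] / [−800, 800] — as the classic
preprocessing does).  A noiseless additive plant has MSR exactly 0 on
its own cells.  The standard benchmark is a 200×40 matrix with three
non-overlapping additive plants of 50/45/40 genes × 28/26/24
conditions and noise SD 10 (plant MSR ≈ 100 ≪ δ = 300): gene sets are
disjoint and jointly cover ~2/3 of the genes, and each plant spans
most conditions, mirroring the reported shape of real cell-cycle
biclusters (large gene sets, near-complete condition sets).  Recovery
is scored as the mean over plants of the best cell-set Jaccard index
against any reported bicluster.

What the generator does **not** emulate: real expression matrices are
globally correlated, so δ-feasible submatrices are abundant and
growing a bicluster by single-gene steps rarely leaves the feasible
region.  A uniform background is the adversarial opposite — feasible
islands are exactly the plants.  Passing tests on this benchmark
therefore exercises discovery-from-nothing, which is *harder* than
the real-data setting; conversely, coverage figures on synthetic data
say little about coverage on real matrices.

## Known limitations

* On the standard benchmark the search reliably localizes and grows
  the leading plant (best per-plant cell Jaccard 0.5–0.7 within 100
  generations) but the mean recovery over all three plants is ~0.2 at
  that budget: growth is a sequence of single-bit moves (each must be
  cloned, improve and survive), advancing ~0.5 bits per generation per
  lineage, so fully recovering three ~60-bit plants needs a few
  hundred generations.  The operator set contains no crossover or
  block node-addition that could make multi-bit in-plant jumps; with
  `generations=250` or larger the benchmark plants are recovered
  substantially further.
* Archive hypervolume is not strictly monotone (see above); the trace
  reported in `RunHistory` is computed against fixed, data-derived
  log-scale bounds so values are comparable across generations.
* The δ threshold is taken as given; nothing in the package estimates
  a data-appropriate δ.
* Missing-value imputation by uniform draws (the classic recipe) adds
  noise that can obscure biclusters overlapping missing cells; the
  missing mask is preserved so downstream analyses can check.
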