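# Methods

This note documents the statistical models, the null algorithms, the
synthetic-data generator and the numerical choices behind
`commassembly`, in enough detail that every number the package produces
can be traced to a definition.

## Input model and preprocessing

The unit of observation is an ASV count table (taxa × samples,
non-negative integers) with a rooted, branch-length-bearing phylogeny
over the taxa, a seven-rank taxonomy (domain … species; absent ranks
are explicit empty markers) and per-sample metadata (position ∈
{floating, settled}, nucleic_acid ∈ {DNA, cDNA}, reactor).

Contaminant filtering removes taxa whose lineage matches a label set
(default {Chloroplast, Mitochondria}) case-insensitively as a substring
at any rank — SILVA places chloroplast reads at order level and
mitochondrial reads at family level, and release-specific strings vary.

Rarefaction subsamples every sample to a common depth (default: the
minimum sample total) **without replacement**, i.e. each rarefied
sample follows a multivariate hypergeometric law over its observed
reads. This matches the common QIIME convention; sampling with
replacement would inflate the variance of rare-taxon counts. Taxa left
with all-zero rows are dropped: unobserved taxa would otherwise enter
the occupancy-weighted nulls with weight zero yet still occupy
dimensions of the randomisation space.

## Alpha and beta diversity

Richness is the count of taxa with positive reads. Shannon entropy is
H = −Σ f ln f in nats (the base is a convention; it cancels in all
comparisons the package makes). Pairwise dissimilarities: Bray–Curtis
Σ|x−y| / Σ(x+y); Jaccard 1 − |shared| / |union| on presence/absence;
Ružička 1 − Σ min(x,y) / Σ max(x,y), which restricted to 0/1 vectors
equals Jaccard exactly (a property test enforces this). Metrics operate
on counts because tables are rarefied to equal depth first; a
`relative=True` flag normalises columns for non-rarefied input.

## NTI — nearest taxon index

For sample i with taxa S_i on a tree with patristic distances d_kl,
MNTD_i = mean over k∈S_i of min_{l∈S_i, l≠k} d_kl (presence/absence
only). The null redraws |S_i| taxa uniformly without replacement from
the pool of taxa observed in at least one sample of the table, 999
times by default. NTI_i = −(MNTD_obs − mean_null) / sd_null. Samples
with fewer than two taxa, or a degenerate null (sd = 0), are reported
as NaN, never silently zeroed.

## βNTI — phylogenetic turnover null

βMNTD between samples x and y is 0.5·[Σ_k f_xk · min_{l∈y} d_kl +
Σ_k f_yk · min_{l∈x} d_kl], abundance-weighted by default (the
unweighted variant is a flag). A taxon present in both samples is its
own nearest neighbour and contributes zero.

The null permutes taxon labels over the patristic distance matrix of
**all tips of the supplied tree**, one permutation per replicate shared
by every sample pair in that replicate (999 reps). Shuffling over the
full tip set, rather than only taxa observed in the analysed table, is
essential: a set of communities confined to one clade has an observed
taxon pool that *is* that clade, and a shuffle restricted to it could
never register the confinement as clustering. βNTI = (obs − mean_null)
/ sd_null; pairs with identical membership have βMNTD invariant under
relabelling (sd = 0) and are flagged undefined. The vectorised
implementation is verified against a naive per-pair loop to 1e-12.

## RC_bray — abundance-based Raup–Crick

For a sample pair inside a regional pool (by default, the sample group
under analysis), each replicate assembles both samples independently:

1. membership — draw the sample's observed richness taxa without
   replacement with probability proportional to occupancy (fraction of
   pool samples containing the taxon), via Gumbel top-k keys;
2. abundance — give each drawn taxon one read, then allocate the
   remaining reads by a multinomial with probabilities proportional to
   pool-wide relative abundance renormalised over the drawn taxa, so
   realised richness always equals drawn richness;
3. score — Bray–Curtis between the two null samples.

RC = 2·[(#null < obs) + 0.5·(#null = obs)]/reps − 1 ∈ [−1, 1]. Because
sample totals are preserved, observed and null Bray–Curtis values are
integer numerators over one common denominator; tie detection is
therefore exact integer comparison, and the half-weight tie rule avoids
bias on the discrete Bray–Curtis lattice.

## QPE classification

Per pair: βNTI > +2 → variable selection; βNTI < −2 → homogeneous
selection; otherwise RC_bray > +0.95 → dispersal limitation, RC_bray <
−0.95 → homogenising dispersal, else undominated. All inequalities are
strict; the boundary values themselves fall through to the weaker call.
Pairs with undefined βNTI are excluded from fraction denominators and
counted separately. Per-group summaries use the group itself as the
regional pool (a flag allows whole-table pools); RC_bray is only
computed for pairs that did not clear the selection threshold.

## NST — normalised stochasticity ratio

Null tables obey a taxa-richness constraint: occurrence probability is
proportional to observed occurrence frequency ("proportional" taxa
constraint); richness is either fixed at the observed value (PF) or a
binomial realisation with expectation equal to observed richness (PP;
clamped to [1, pool size, sample total] so no null sample is empty).
For abundance metrics, reads are allocated like the RC null, preserving
totals.

With D_ij observed and E_ij the mean null dissimilarity (1000 reps):

- D ≥ E: ST = E/D, NST = (ST − E)/(1 − E)
- D < E: ST = (1−E)/(1−D), NST = (ST − (1−E))/E

Both branches give NST = 1 at D = E and decrease monotonically to 0 as
D departs toward either extreme; the formulas are continuous at D = E.
Edge cases are resolved by limits: D = E (including both 0) → NST = 1;
E ∈ {0, 1} with D ≠ E → NST = 0. Group NST is the mean over
within-group pairs, reported as a percentage. These ST/NST expressions
are the package's reconstruction of the stochasticity-ratio contract
(unity at the null expectation, zero at maximal deviation,
branch-symmetric); they are isolated in one function
(`nst._nst_from_d_e`) so they can be swapped if cross-validation
against another implementation ever requires it.

**PANOVA.** The statistic is the absolute difference of within-group
mean pairwise NST (the range of group means when more than two groups
are supplied — the two-group case is the canonical one). The null
permutes sample-to-group labels and recomputes the statistic from the
precomputed pairwise NST matrix; p = (1 + #null ≥ obs)/(1 + permutations).
Note the resolution limit of label permutations: with two groups of 4
the smallest attainable p is ≈ 0.03, so designs needing p ≤ 0.01 require
at least 6 samples per group.

## Competitive lottery model

Clades are taxonomy ranks (default family). A clade is eligible in a
sample when it holds at least `min_clade_reads` reads (default 10 — the
floor keeps one-read clades from producing trivial winners; it is
configurable). The clade's most abundant ASV is the winner iff its
share strictly exceeds the threshold (default 0.90); a share of exactly
0.90 is not a win. Winner prevalence = winners / eligible samples.
Winner diversity = H(p)/ln(S_w) where p are the frequencies of distinct
winner identities over the S_w winner-containing samples; defined 0
when S_w ≤ 1 or one ASV always wins. The entropy form reproduces the
intended qualitative behaviour (0 = one dominating ASV, →1 = maximally
varied winners); other formalisations exist, so it too is isolated in
one function. Winner-status comparison labels each clade winner-in-all,
winner-in-subset (with categories listed) or no-lottery-behaviour.

## Synthetic communities with known assembly regimes

The generator exists to answer one question: when data are assembled by
a known process, does each statistic recover it? Components:

- **Tree**: pure-birth (Yule) with rate 1, exponential waiting times,
  a closing interval so all branch lengths are positive.
- **Trait**: Brownian motion along branches (child = parent +
  N(0, σ²·t), root 0). The *conserved trait* of a tip is the Brownian
  value at its ancestor at 50 % of maximum root-to-tip depth — constant
  within each deep clade by construction.
- **Pool**: i.i.d. log-normal relative abundances over tips.

Regimes (defaults: 128-tip tree, 10 samples, depth 2000):

- *homogeneous selection* — one shared Gaussian niche on the
  **conserved** trait. The optimum is the conserved value of the deep
  clade whose size is closest to a quarter of the pool, and the width
  (0.05 × sd of the conserved trait) excludes convergent clades without
  excluding clade members. Selecting on raw tip traits does not work on
  trees of this size: Brownian tails mix lineages, and the resulting
  niches are too phylogenetically incoherent for βNTI to flag reliably.
- *variable selection* — two sample blocks with raw-trait optima at
  median ± 2 sd (4 σ apart), same Gaussian filter (width 0.5).
- *dispersal limitation* — taxa split into disjoint subpools; each
  sample seeded from its subpool, then 20 generations of Wright–Fisher
  multinomial drift with migration m = 0.001 from the metacommunity.
- *homogenising dispersal* — one "mother" community drawn from the pool
  (10× depth), every sample a multinomial resample of it (mass
  effects).
- *pure drift* — i.i.d. multinomial draws from the pool.
- *nst_null* — a drift table passed through the PF stochasticity null,
  for NST self-calibration.

Both selection regimes add per-sample turnover: each niche member
establishes with probability 0.5 (establishment lottery) and its weight
is jittered log-normally (σ = 0.75). Without this, replicate samples
from one selective environment are near-identical, and a pair with
identical membership carries *no* information for βMNTD — shared taxa
contribute zero under every tip relabelling — so selection would be
undetectable by construction. The establishment/jitter levels were
chosen so that membership turnover is substantial while the weighted
βMNTD still averages over enough taxa to have low null variance.

Pool evenness is regime-resolved: selection regimes use log-normal
σ = 0.5, dispersal and drift regimes σ = 2.0 (homogenising dispersal
2.5, the nst_null calibration scenario 1.0). This reflects where each
signature lives in real data: abundance-weighted βNTI needs turnover
spread across many comparably-abundant niche members, whereas the
occupancy-conditioned Raup–Crick null can only register mass effects
through a rare-taxon occupancy tail — with a near-even pool every taxon
is everywhere and observed and null assemblages coincide.

What the generator does **not** emulate: compositionality artefacts of
relative sequencing depth, PCR/primer bias, chimeras or any read-level
error (tables are exact multinomial draws), sequence-level ASV
uncertainty, or time-series autocorrelation. Passing recovery tests
therefore demonstrates statistical correctness of the inference chain
on idealised count data, not robustness to sequencing artefacts.

The 24-sample preset arranges 2 positions × 2 nucleic acids × 3
reactors (12 samples per position sharing one assembly regime each) and
derives a synthetic taxonomy by cutting the simulated tree at 30 %
(family) and 60 % (genus) of maximal depth, so clade-level analyses run
on simulated data end to end.

## Reproducibility and problem sizes

Every stage seed is derived as SHA-256(global_seed | stage tags) mod
2³¹, so adding a stage never perturbs another stage's randomness, and a
pipeline rerun with the same seed is byte-identical (timings go to a
separate log file). Null replicates default to 999 (NTI, βNTI, RC) and
1000 (NST).

The test suite and the acceptance script use deliberately scaled
problem sizes chosen to keep the statistical checks well-powered while
remaining quick: recovery experiments use the default 128-tip/10-sample
scenarios over 3–5 seeds (45 pairs each); calibration experiments use
64-tip trees with ~200 replicate draws per null; the study-shaped
pipeline run uses a 400-taxon pool at depth 3000 with 299 null
replicates. All such sizes are stated next to the numbers they produce.

## Known limitations

- The richness null for NTI draws from taxa observed in the analysed
  table; with very few samples the pool itself is biased toward the
  communities being tested, which is conservative.
- RC_bray inherits the discreteness of Bray–Curtis at low depth;
  at depth ≳ 500 the tie mass is negligible.
- The NST normalisation is a reconstruction (see above); absolute NST
  levels should not be compared across implementations without
  cross-checking the formulas.
- PANOVA assumes exchangeability of samples across groups under the
  null; nested designs (e.g. reactor within position) are not modelled.
- Lottery winner diversity depends on the entropy formalisation chosen
  here; rank-based alternatives would order clades similarly but not
  identically.
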