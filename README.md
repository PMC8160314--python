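# commassembly

Null-model analysis of microbial community assembly for 16S ASV
datasets: which ecological processes — selection, dispersal, drift —
shaped the communities you sequenced?

The package was built around the study design of anaerobic granular
sludge bioreactors, where floating and settled biofilm granules host
distinct microbiomes and the question is which assembly mechanisms
drive the difference. Everything is generic, though: any ASV count
table with a rooted phylogeny, taxonomy and sample metadata works.

## What it computes

Four complementary null-model lenses, applied per sample or per sample
pair:

* **NTI** (nearest taxon index): for each sample, the negative z-score
  of its mean nearest-taxon distance (MNTD) against a richness-
  preserving randomisation (999 reps). NTI > +2 means phylogenetic
  clustering — strong environmental filtering; NTI < −2 suggests
  competition-driven overdispersion.
* **QPE** (quantitative process estimates): per sample pair, βNTI — the
  z-score of abundance-weighted βMNTD against a tip-shuffling null —
  assigns *variable selection* (βNTI > +2) or *homogeneous selection*
  (βNTI < −2). Pairs without a selection signal are split by the
  abundance-based Raup–Crick metric on Bray–Curtis, RC_bray ∈ [−1, 1]:
  *dispersal limitation* (> +0.95), *homogenising dispersal* (< −0.95),
  otherwise *undominated*. All bounds are strict.
* **NST** (normalised stochasticity ratio): compares each observed
  dissimilarity D_ij (Jaccard or Ružička) with its expectation E_ij
  under proportional-proportional or proportional-fixed taxa-richness
  nulls, and rescales so NST = 1 at D = E (pure stochasticity) and 0 at
  maximal deviation. Group differences are tested with a permutation
  test over sample labels ("PANOVA").
* **Competitive lottery model**: within each family-level clade, an ASV
  capturing > 90 % of the clade's reads in a sample is that sample's
  lottery *winner*; winner prevalence and winner diversity (normalised
  entropy of winner identities) summarise clade-level competition, and
  winner status is compared across sample categories.

A synthetic-data module generates communities with known ground truth
(pure-birth phylogenies, Brownian niche traits, log-normal regional
pools, and six assembly regimes), so every statistic can be validated
against data whose generating process is known. See `docs/methods.md`.

## Worked example

```python
import commassembly as ca
from commassembly.qpe import QPEConfig, qpe_pairs

# a 10-sample community assembled under homogeneous selection
ds = ca.simulate_dataset(ca.Scenario(regime="homogeneous_selection", seed=1))
pairs = qpe_pairs(ds.table, ds.tree, QPEConfig(reps=999, seed=7))
print(pairs["process"].value_counts(normalize=True).round(3))
nst = ca.stochasticity(ds.table, metric="ruzicka", constraint="PF",
                       reps=1000, seed=7)
print(f"group NST: {nst.group_nst_percent:.1f}%")
```

prints

```
homogeneous_selection    0.822
dispersal_limitation     0.089
undominated              0.089
group NST: 47.9%
```

82 % of sample pairs are correctly assigned to homogeneous selection
(their βNTI falls below −2: turnover is far more phylogenetically
conserved than the tip-shuffle null expects), and the NST of ~48 %
shows that a deterministic regime still leaves roughly half of the
pairwise turnover within null expectations.

The same analyses run from the shell on your own files:

```bash
commassembly run --config analysis.yaml --seed 42
commassembly simulate --regime dispersal_limitation --seed 7 --out sim/
commassembly nti --table table.tsv --tree tree.nwk --seed 1 --out out/
```

`run` executes the full pipeline (contaminant filtering → rarefaction →
alpha diversity → NTI → QPE → NST + PANOVA → lottery) and writes TSV
tables, a JSON summary and a run manifest; reruns with the same seed
are byte-identical.

## Layout

- `commassembly.io` — TSV/Newick readers and writers, contaminant
  filtering, rarefaction
- `commassembly.metrics` — richness, Shannon entropy, Bray–Curtis,
  Jaccard, Ružička
- `commassembly.phylo` — cophenetic distances, MNTD/NTI, βMNTD/βNTI
- `commassembly.qpe` — RC_bray and the five-way process classification
- `commassembly.nst` — stochasticity-ratio nulls and PANOVA
- `commassembly.lottery` — clade winners, prevalence, diversity
- `commassembly.simulate` — the ground-truth community generator
- `commassembly.pipeline` / `commassembly.cli` — orchestration and the
  `commassembly` command
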