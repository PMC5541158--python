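# traitsignal

Tools for analyzing curated bacterial phenotype databases: how strongly are
measured traits conserved on the 16S phylogeny, and which genes track a
strain's environmental preferences?

Strain descriptions published in IJSEM (the journal of record for novel
prokaryotic taxa) carry a wealth of phenotypic and environmental-tolerance
information — Gram stain, cell shape, spore formation, habitat, oxygen
requirement, and growth ranges/optima for pH, temperature and salinity.
Once such records are compiled into a table and joined to a 16S rRNA
phylogeny and to genome content, three questions become tractable, and this
package implements the full pipeline for all three:

1. **Curation and summarization** (`trait_db`): parse and validate the
   strain table, harmonize free-text trait mentions (e.g. "nitrate
   reducer" and "positive for nitrate reduction" are the same process),
   derive environmental optima from ranges (midpoint rule when only a
   range is reported), and tabulate trait distributions with per-trait
   reporting counts.
2. **Phylogenetic signal** (`phylo`, `signal`): for a continuous trait *x*
   on a tree with phylogenetic covariance matrix **V** (V<sub>ij</sub> =
   shared root-to-MRCA path length), Blomberg's

   *K* = (MSE<sub>0</sub>/MSE) / E<sub>BM</sub>[MSE<sub>0</sub>/MSE],

   where MSE<sub>0</sub> and MSE are the error sums around the GLS mean
   â = (**1**′**V**⁻¹x)/(**1**′**V**⁻¹**1**) without and with **V**
   weighting, and the expectation under Brownian motion is
   (tr **V** − n/**1**′**V**⁻¹**1**)/(n−1).  K = 1 matches Brownian
   motion; K ≈ 0 means no signal.  For a binary trait, Fritz–Purvis

   *D* = (d<sub>obs</sub> − mean d<sub>Brownian</sub>) / (mean d<sub>random</sub> − mean d<sub>Brownian</sub>),

   where d is the sum of sister-clade differences of nodal estimates;
   D is reported as **−D + 1** so that 0 = no signal and larger = more
   conserved, directly comparable with K.  Significance for both comes
   from permuting trait values across the tips (default 1,000 times).
3. **Gene-content enrichment** (`genome_link`, `enrichment`): link strains
   to sequenced genomes by 16S similarity (identity > 99% and coverage >
   95%, best hit per strain), build a strains × KEGG-ortholog
   presence/absence matrix, and fit one logistic regression per KO,
   P(KO present) = expit(β₀ + β₁·optimum), against the strain's pH or
   salinity optimum.  Slopes significant after Bonferroni correction
   (α = 0.05 over all fitted models; 7.3e−6 at the 6,889-model study
   scale) mark putative genotype–phenotype links, which are then
   classified as transporters by TCDB membership.

A seeded generator (`synthetic_data`) produces complete synthetic studies —
Yule trees, Brownian/white-noise/threshold/shuffled traits, strain tables
with range-only reporting and missingness, and KO matrices with planted
logistic effects — in exactly the file formats the pipeline reads, so every
stage is testable with known ground truth.

## Worked example

```python
from traitsignal import synthetic_data as syn
from traitsignal.signal import signal_table

tree = syn.simulate_tree(128, seed=7)                     # Yule tree
bm    = syn.simulate_trait(tree, "bm", seed=6, name="temperature_optimum")
spore = syn.simulate_trait(tree, "threshold", prevalence=0.3, seed=8, name="spore")
noise = syn.simulate_trait(tree, "white_noise", seed=9, name="ph_optimum")

table = signal_table(tree, [bm, spore, noise], n_perm=999, alpha=0.05, seed=10)
print(table.drop(columns="note").to_string(index=False))
```

```
              trait        type  statistic  p_value   n  significant
temperature_optimum  Continuous   1.104498    0.001 128         True
              spore Categorical   1.191782    0.000 128         True
         ph_optimum  Continuous   0.013599    0.934 128        False
```

The Brownian trait comes out with K ≈ 1 and a significant permutation
p-value; the threshold-model binary trait shows strong signal on the −D+1
scale; the white-noise trait is correctly indistinguishable from a random
assignment of values to tips (statistic near 0, large p).

The same analyses are available from the shell:

```bash
traitsignal simulate --n-tips 200 --n-kos 500 --n-planted 5 --seed 1 --outdir fixtures/
traitsignal signal   --tree fixtures/tree.nwk --traits traits.tsv --n-perm 1000 --seed 1 --out table_signal.tsv
traitsignal enrich   --ko-matrix fixtures/ko_matrix.tsv --optima optima.tsv --trait ph --out table_enrich.tsv
```

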