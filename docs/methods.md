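# Methods

## Scope and data model

The package operates on three joined resources: a curated strain phenotype
table (one row per described strain, IJSEM-style fields), a rooted 16S
phylogeny whose tip labels are strain ids, and a strains × KEGG-ortholog
(KO) presence/absence matrix obtained by linking strains to sequenced
genomes.  Missing information is always `None`, never a sentinel value;
every statistic drops absent values for its own trait and reports the
per-trait n actually used.

### Curation rules

* Controlled vocabularies (shape, aggregation, habitat, oxygen) accept the
  packaged categories; unknown categories are mapped to `other` with a
  warning rather than rejected, since strain descriptions routinely invent
  new terms.  Tri-state fields (Gram stain, motility, flagella, spore,
  pigment) parse a generous synonym set; unrecognized spellings become
  unknown with a row-level warning.
* Field invariants: GC content in [0, 100], pH in [0, 14], cell dimensions
  ≥ 0, range min ≤ max.  Violations drop the offending value (not the row)
  and are reported with row number, field and reason.  Duplicated strain
  ids are flagged but both rows are kept, leaving resolution to the
  curator.
* Free-text trait mentions are harmonized through term maps
  (canonical trait, synonym list, polarity); matching ignores case and
  punctuation.  Synonym lists must be disjoint across canonical traits and
  this is checked at load time.
* Environmental optimum: the explicitly reported optimum wins; when a
  trait is reported only as a (min, max) range the midpoint (min+max)/2 is
  used.  An explicit optimum outside its own reported range is kept but
  warned about.  Units are fixed (pH units, °C, % NaCl w/v).

## Phylogenetic signal

### Trees

Newick parsing, midpoint rooting and taxon pruning are delegated to
dendropy; the wrapper enforces unique tip labels, nonnegative branch
lengths, and defaults missing branch lengths to 1.0 with a warning.
Midpoint rooting never changes tip-to-tip distances (tested), and pruning
suppresses the degree-2 nodes it creates with branch lengths summed, so
patristic distances among retained tips are invariant.  Polytomies are
retained.  The phylogenetic covariance matrix V has V[i,j] = depth of the
MRCA of tips i and j; it is computed in one postorder pass and is the
single quantity the continuous-trait statistic consumes.

### Blomberg's K

With W = V⁻¹ (Cholesky solve; a pseudoinverse with tolerance 1e-10 and a
warning when V is singular, e.g. zero-length terminal branches):

    â    = (1'Wx)/(1'W1)
    MSE0 = (x−â)'(x−â)/(n−1)
    MSE  = (x−â)'W(x−â)/(n−1)
    K    = (MSE0/MSE) / [(tr V − n/(1'W1))/(n−1)]

K is invariant under affine transforms of the trait and equals 1 exactly
on star trees (V = I), both tested to 1e-9.  Significance uses tip
permutation with MSE as the statistic and a one-sided smaller-MSE-is-
signal rule, p = (1+r)/(n_perm+1).  Under exchangeable traits this p is
uniform on its achievable grid; with n_perm = 99 the rejection rate at
α = 0.05 is exactly 0.05 in expectation, which the calibration test
verifies at 1,000 replicates against the exact binomial 99% interval.

### Fritz–Purvis D and the −D+1 transform

The observed statistic d_obs sums |est(left) − est(right)| over internal
nodes, with nodal estimates from a tips-to-root pass of equal-weight
daughter averaging.  Branch lengths are deliberately ignored in this pass
(the construction is topological); they still drive the Brownian null
simulated on the same tree.  Polytomies are resolved for this pass only,
into a deterministic left-to-right ladder of zero-length branches, because
sister-clade differences require bifurcations; the resolution is recorded
in the result metadata.

Two nulls, each with n_sims replicates: (a) uniform shuffles of the tip
values; (b) Brownian motion on the tree, rank-thresholded per replicate so
that every replicate has exactly the observed number of 1-tips (ties at
the cutoff break by tip-label order, making the thresholding a
deterministic function of its input).  Then

    D = (d_obs − mean_brownian) / (mean_random − mean_brownian)

and −D+1 is reported alongside for comparability with K (0 = no signal).
Both one-sided p-values (fraction of null replicates with d ≤ d_obs) are
kept on the result; the tabulation layer reports the shuffle p by default,
matching the tip-permutation significance convention used for K.

Degenerate normalization (the two null means coinciding, possible on very
small trees at small n_sims) raises with diagnostics rather than returning
an unstable ratio.

### Calibration

Under their own generative models the estimators are unbiased at the
tested scales: mean K over 200 Brownian traits on a 128-tip Yule tree
falls in [0.9, 1.1]; mean D over 500 shuffled binary traits on a 64-tip
tree falls within 1 ± 0.1 and over 500 Brownian-threshold traits within
0 ± 0.1.  These replicate counts, and the 100 null simulations per D
evaluation used inside the calibration loops, are the package's reduced
calibration profile; single-analysis defaults remain n_perm = n_sims =
1,000.

## Genome linking and the KO screen

Strain–genome links come from a precomputed 16S hit table (query, subject,
percent identity, alignment length, query length; coverage = aligned
fraction of the query).  Both thresholds are strict (identity > 0.99,
coverage > 0.95) and configurable; one best hit per strain is kept
(highest identity, then coverage, then lexicographic genome id) because
the regression needs one KO profile per strain.  The KO matrix cell is 1
iff the KO is annotated in the linked genome; columns are the union of KOs
over linked genomes.

The enrichment screen fits, per testable KO (present in ≥1 and absent in
≥1 analyzed strain), a two-parameter logistic regression of presence on
the trait optimum by Newton/IRLS (log-likelihood tolerance 1e-8, 100
iterations, step-halving).  Strains without the optimum are dropped once,
listwise, before any fit.  Inference on the slope is a two-sided Wald test
by default; a likelihood-ratio test is available behind a flag.  Complete
or quasi-complete separation is detected (diverging logits with a
still-improving likelihood, or a singular Hessian) and flagged; separated
KOs are excluded from the significant set but still counted in the
Bonferroni family m, since they were fitted — a conservative choice.
m defaults to the number of testable KOs in the current run and can be
overridden (`--n-models`) to apply a cutoff computed for a larger
published family.  The applied cutoff α/m is asserted internally.

Each trait (pH, salinity) is screened independently; a KO significant for
both traits counts toward both in the summaries, where transporter
fractions are percentages rounded half-up.  Transporter classification is
closed-world membership in a packaged TCDB snapshot covering the packaged
marker set; users supply their own list for larger screens.

Calibration: the Wald test's type-I error at n = 200 sits inside the exact
binomial 99% interval around 0.05 over 1,000 simulated null datasets; with
|β₁| = 2 (per trait unit, centered covariate) and n = 400, all five
planted KOs among 300 nulls are recovered with correct signs in ≥ 90% of
seeded runs; and the fully null screen's family-wise error under
Bonferroni stays at or below 0.05 plus binomial noise over 200 runs.

## Synthetic data

The generator emulates the statistical structure of a curated strain
database, not its text:

* **Trees**: Yule (pure birth), exponential waiting times at rate
  k·birth_rate with k extant lineages, cut when the (n+1)-th lineage would
  arise; mean root-to-tip depth matches Σ_{k=2..n} 1/(k·birth_rate) to
  within 10% over 1,000 trees (tested).  A pure-birth model suffices
  because the signal statistics condition on the tree.
* **Traits**: Brownian (variance rate σ²·branch length), white noise,
  Brownian-threshold at a target prevalence, and uniform shuffles.
* **Strain tables**: latent pH optima uniform(4, 9) — the neutrophile-
  dominated spread typical of strain descriptions; salinity optima
  lognormal(0.5, 1) % NaCl (median ≈ 1.6%, right-skewed, capped at 30%);
  temperature optima normal(30, 8) °C.  A configurable fraction of
  records report each optimum only as a symmetric ±1-unit range around the
  latent value, exercising the midpoint rule; per-field missingness is
  configurable and defaults to 0.
* **KO matrices**: planted KOs are Bernoulli(expit(β₀ + β₁·(optimum −
  mean optimum))) with alternating slope signs; the covariate is centered
  so β₀ stays interpretable as baseline log-odds regardless of the trait's
  scale.  Null KOs are Bernoulli(p), p ~ uniform(0.05, 0.95) per KO.
  Ground truth (planted ids and signs) is returned and written to the
  fixture manifest.

All generators are bit-reproducible from (parameters, seed), and the
fixture writer emits the same file formats the parsers read, so round-trip
tests exercise real I/O paths.

What the synthetic calibrations do **not** show: real strain tables have
phylogenetically structured missingness, correlated traits, measurement
heterogeneity across labs and decades, and 16S trees with estimation
error; Yule trees are ultrametric while real FastTree-style trees are not.
Passing calibration here demonstrates correctness of the estimators under
their stated models, not robustness to those real-data features.

## Numerical choices

* V inversion by Cholesky; pseudoinverse (rcond 1e-10) fallback with a
  warning for singular V.
* Permutation/simulation p-values: add-one convention for K's permutation
  test; raw fractions for D's null exceedances.
* Threshold ties: tip-label order.  Midpoint-rooting ties: resolved
  deterministically by the rooting routine.  Polytomy resolution for D:
  left-to-right ladder, zero-length branches.
* Logistic separation guard: |logit| > 30 with improving likelihood, or a
  singular Hessian.
* All seeds below 2³¹; nested analyses derive child seeds via
  `numpy.random.SeedSequence.spawn`.

## Known limitations

* D's p-values are simulation-based and share the n_sims resolution; very
  small trees can degenerate (both null means equal), which raises rather
  than guesses.
* The screen fits univariate models per trait; no phylogenetic correction
  of the regressions (gene content and environmental preference are both
  heritable on the tree, so significant KOs are putative links, not causal
  claims).
* The packaged TCDB snapshot covers only the packaged marker set; genuine
  transporter classification for new screens requires a full membership
  list.
* Term maps ship with a small starter vocabulary; real curation requires
  extending them.
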