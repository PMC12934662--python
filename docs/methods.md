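# Methods

## Generative model of the synthetic data

`amgrn.syndata` emulates a two-population LPS-challenge timecourse
(timepoints d0, d3, d6, d15 by default) with planted ground truth at every
level the inference chain touches.

**Topics.** K = 3 topic gene distributions (homeostasis, inflammation,
resolution) are built from gamma-distributed weights with an 8× boost on a
per-topic signature block of non-TF genes (96 genes per block at the
default 500 genes / 20 TFs).  TFs collectively carry `tf_mass_share = 0.15`
of every topic's mass with a mild per-topic lognormal tilt
(`tf_topic_sd = 0.1`); the master TF (TF00) additionally gets a 4× weight
in the homeostasis topic so that its activity varies along the homeostasis
axis rather than forming an expression factor of its own.  Per-cell topic
proportions are Dirichlet draws (concentration 30) around population ×
timepoint means: the resident-like population stays predominantly
homeostatic with a weak inflammation bump at d3; the recruited-like
population swings to 0.70 inflammation at d3 and 0.50 resolution at d6.

**Networks.** Directed TF–TF edges are Bernoulli per ordered pair with
density 0.30 (resident-like) versus 0.05 (recruited-like) — the density
contrast is the only network difference between populations.  Every TF
additionally regulates 25 random non-TF genes with signed weights
±Uniform(0.2, 1) × `edge_weight_scale` (default 0.6), shared between
populations.  The master TF instead drives 40 homeostasis-block genes with
+Uniform(0.35, 0.7) × scale and 40 inflammation-block genes with the
negated range — signs fixed by construction.

**Counts.** Per cell, the rate vector is the topic mixture.  TF log-rates
receive a Gaussian activity fluctuation (`tf_activity_sd = 0.3`) and one
pass of TF–TF coupling; non-TF targets receive the signed weighted sum of
their regulators' within-population standardized activities.  Every
coupling term is made mean-preserving on the rate scale by subtracting
half its empirical variance on the log scale — network effects perturb
individual cells without biasing the marginal topic gene distributions,
which keeps topic recovery and edge recovery simultaneously well posed.
Observation noise (`noise_sd`, default 0.2) is added to every gene's
log-rate *after* coupling, so it degrades recovery without carrying any
regulatory signal.  Rates are renormalized and counts drawn multinomially
at a Poisson library size (mean 5,000 — deep coverage, appropriate for a
500-gene targeted panel where per-gene depth matters).  Eight constitutive
marker genes per population (×6 up in the own population, ÷5 in the other)
play the role of origin markers and anchor the k-means population
annotation.

**Sequences.** One 300-bp contig per gene holds a single 200-bp peak and a
downstream TSS.  One 8-mer consensus motif per TF is embedded in the peaks
of that TF's target genes (plus 15 decoy placements per TF on non-target
genes — motif presence without regulation, which is exactly what the
regression stage must filter), and two annotation-only motifs are planted
exclusively near homeostasis or inflammation signature genes.  Background
bases are i.i.d. uniform ACGT, re-drawn until no catalog PWM scores within
0.5 of the scan threshold anywhere off-ledger, so the placement ledger is
the complete set of scannable sites.  PWMs are sharp (997:1 counts per
position), which with the log₂ log-odds threshold of 10 makes only exact
consensus matches scannable at 8 bp.

## Inference settings

- Topic model: multiplicative Poisson-NMF (EM), 150 main + 150 refinement
  iterations.  Five starts are initialized by k-means++-style seeding of
  the gene factors from mutually distant cell profiles and the
  best-likelihood incumbent after the main iterations is refined.  Plain
  random single starts frequently converge to a lower-likelihood optimum
  that splits the dominant homeostasis program across two topics and
  merges inflammation with resolution; selecting across anchored starts by
  likelihood resolves this.  The log-likelihood trace (up to the `log x!`
  constant) is non-decreasing within each EM run.
- Grade-of-membership LFC: `log2((F + ε)/(baseline + ε))` with
  `ε = 1e-8` and baseline the loadings-weighted mean of `F` across topics.
  This is a deliberately simpler contrast than posterior-based
  differential-expression estimates; it preserves ranking behavior, which
  is all the top-gene lists consume.
- Gene selection: ≥ 1 total count, variance of log1p counts-per-10k, top
  2,500 by default (capped at the gene count on synthetic panels), unioned
  with the TF list.
- Imputation: 47 principal components (deterministic full-SVD PCA, sign
  fixed by the largest loading), k = 2.5 % of cells, self included, mean
  over neighbors.
- Network regression: per target, ridge (λ = 1 on standardized regressors)
  over 20 bootstrap resamples; an edge is retained when |bagged mean| /
  bootstrap SE > 2 and the sign agrees in ≥ 80 % of resamples.
  Coefficients are also rescaled to expression units
  (× sd(target)/sd(regulator)) for the knockout propagation.  Networks are
  fitted per population × timepoint (≥ 50 cells per context); when edges
  are ranked across a population, the per-timepoint |coefficients| are
  averaged.
- Centrality: power iteration on the undirected absolute-weight adjacency
  of retained edges with a 0.1·max-degree diagonal shift (bipartite
  subgraphs otherwise oscillate), tolerance 1e-10, max-normalized.
  Directed left/right variants are available behind `mode=`.
- Knockout screen: 3 propagation steps, cumulative shift clamped so
  simulated expression stays ≥ 0 and the knocked-out TF stays at zero.
  Projection uses 200 expression-space neighbors (PCA space, the same
  space as imputation), an exponential kernel at temperature 0.05 on the
  delta–neighbor correlations, and subtracts the uniform-neighbor mean to
  remove embedding-density bias.  Fields are smoothed onto a 40 × 40 grid
  with a Gaussian bandwidth of 1/25 of the larger bounding-box side; a
  topic score is the occupied-node mean dot product between the knockout
  field and the topic-loading gradient (central differences, one-sided at
  mask borders).  The mean (not sum) keeps scores comparable across
  populations with different cell counts; this choice is recorded in the
  run report.
- Motif scanning: log₂ odds against a strand-symmetrized background
  estimated from the scanned sequences (uniform available via a flag),
  pseudocount 0.01 per frequency cell, both strands, same-strand overlaps
  resolved by score.  Peak→gene windows of 3 kb (base GRN) and 100 kb
  (topic contrast) are separate first-class parameters; distance is
  measured from the closest covered peak base to the TSS.

## What the tests demonstrate — and what they do not

The acceptance suite (`tests/test_acceptance.py`) shows, on data with
planted truth: topic recovery (Hungarian-matched cosine ≥ 0.9, mean over
five 2,000-cell-per-population simulations); candidate-edge AUROC ≥ 0.85
against decoy motif sites; a monotone increase of the planted-edge miss
rate along the observation-noise ladder 0.05 → 0.2 → 0.5; higher mean TF
centrality in the dense population at every timepoint (≥ 8/10 seeds);
larger mean knockout magnitudes in the sparse population (≥ 8/10); and the
master-TF knockout signature — negative homeostasis score, positive
inflammation score, above-average magnitude — in the resident-like
population (≥ 8/10).  Exact-oracle tests pin the knockout propagation to
`Σₜ ΔX⁰Wᵗ` on DAGs, KNN imputation to brute-force all-pairs neighbors,
PWM hits to an all-offset rescoring loop, and hypergeometric p-values to
the closed form.

The generator reproduces the *statistical shape* of the study design, not
real single-cell data: no doublets, no ambient RNA, no batch effects,
log-normal rather than empirically-calibrated overdispersion, linear
regulatory effects, and motifs planted at known offsets in short clean
contigs.  Passing these tests shows the inference chain is implemented
correctly and is sensitive to the planted architecture under realistic
noise; it does not certify performance on real tissue data.

### Noise-ladder metric

The ladder uses the planted-edge *miss rate* (fraction of true edges not
passing the retention filter, averaged over timepoint contexts and both
populations, on unimputed normalized expression).  A correlation-based
coefficient error is insensitive here for two structural reasons:
observation noise attenuates all coefficients of a TF by a common factor
(invisible to correlation), and in the dense population the dominant error
is credit-splitting among collinear TFs, which extra noise *relieves*.
The miss rate tracks the bootstrap standard error directly and is monotone
in the noise per seed.  KNN imputation is bypassed for the ladder because
averaging over neighbors removes most i.i.d. observation noise, which is
the quantity the ladder varies.

### Problem sizes

Topic recovery runs 5 seeds at the full 2,000 cells/population; edge AUROC
one seed at 2,000; the noise ladder 3 seeds × 3 noise levels at 600;
centrality contrasts 10 seeds at 1,000 (contexts of 250 cells — at 125
cells per context centrality estimates are too unstable for a reliable
per-timepoint comparison); knockout screens 10 seeds at 600.  These sizes
are the package's choice of desk-scale replication; all inference
parameters keep their full-scale defaults throughout.

## Known limitations

- Eigenvector centrality concentrates on the component with the largest
  leading eigenvalue; in very sparse contexts the recruited-like network
  can fragment, which is the realistic regime but makes per-context means
  noisy below ~200 cells.
- The embedding-projection statistic is a heuristic transition model; its
  scores are comparable within a run (fixed grid, bandwidth, temperature)
  but have no absolute units.
- `simulate_counts` couples TF–TF effects in a single pass over base
  activities; feedback loops longer than one step are not simulated (the
  fitted networks may still contain them).
- With fewer than three true topics the master-TF construction is skipped
  (it needs distinct homeostasis and inflammation programs).
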