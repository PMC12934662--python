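# amgrn

Topic modeling, gene-regulatory-network (GRN) inference and systematic
in-silico transcription-factor (TF) knockout screening for single-cell
RNA-seq, together with a planted-truth synthetic data generator that makes
the whole inference chain testable end to end.

## The scientific problem

Tissue-resident alveolar macrophages respond to an inflammatory challenge
far more moderately than monocyte-derived macrophages recruited into the
same tissue, and one candidate explanation is architectural: a densely
interconnected TF–TF regulatory core buffers the transcriptional program of
the resident cells, while the sparser network of recruited cells lets a
single perturbed TF produce a large functional swing.  Probing that idea
computationally takes a chain of methods:

1. **Grade-of-membership topic model.** Counts are factorized as
   `X ~ Poisson(W H)` by multiplicative (EM) updates and reparametrized so
   each cell is a mixture `L` over K topics (row-stochastic) and each topic
   a distribution `F` over genes (column-stochastic).  Topics are read as
   functional programs — homeostasis, inflammation, resolution — via the
   log₂ fold change of `F[:, k]` against a loadings-weighted baseline and
   gene-set enrichment of the top genes.
2. **Context-specific GRNs.** A candidate edge set (the *base GRN*) comes
   from PWM motif hits in accessible peaks near gene transcription start
   sites; within each cell context (population × timepoint), every gene is
   regressed on its candidate TFs (ridge, bootstrap-bagged) over
   KNN-imputed expression.  Edges are kept when the bagged coefficient is
   sign-stable and large against its bootstrap standard error.  Eigenvector
   centrality of the retained network measures how embedded each TF is.
3. **In-silico knockouts.** Setting a TF to zero and propagating the delta
   through the network coefficients (`ΔX Σₜ Wᵗ`, clamped at zero
   expression) predicts a per-cell expression shift, which is projected
   onto a 2-D embedding via correlation with expression differences toward
   each cell's neighbors.  The mean dot product of that vector field with a
   topic's loading gradient is the TF's *perturbation score* for the topic;
   the Euclidean norm of the (homeostasis, inflammation) score pair is the
   knockout's score-vector magnitude.

The synthetic generator (`amgrn.syndata`) plants all of this structure —
topic gene distributions, population × timepoint mixing proportions, signed
TF→target weights with a dense-vs-sparse TF–TF core, a "homeostasis master
TF" that drives homeostasis genes up and inflammation genes down, marker
genes, and motif instances inside per-gene regulatory peaks — and records
every planted fact in a `GroundTruth` ledger that downstream tests score
against.

## Worked example

```python
from amgrn.pipeline import RunConfig, run_all

report = run_all(RunConfig(
    outdir="amgrn_demo", seed=1,
    synthetic=dict(n_cells_per_population=600),
    grn_group_by=("population",),
))
c = report["contrasts"]
print(round(report["topic_recovery_cosine"], 3))
print({k: round(v, 3) for k, v in c["mean_tf_centrality"].items()})
print({k: round(v, 4) for k, v in c["mean_score_magnitude"].items()})
print({k: round(v, 4) for k, v in
       c["master_tf"]["resident-like"]["scores"].items()})
```

On one CPU this simulates 1,200 cells × 500 genes, fits the topic model,
scans motifs into a base GRN, fits population networks and screens all 20
TFs, printing:

```
0.961
{'recruited-like': 0.133, 'resident-like': 0.222}
{'recruited-like': 0.0233, 'resident-like': 0.0118}
{'score_k1': -0.0245, 'score_k3': 0.0226}
```

Read: the fitted topics match the planted ones (cosine 0.96); TFs sit more
centrally in the dense resident-like network (0.222 vs 0.133); an average
knockout moves the sparse recruited-like population about twice as far
(0.0233 vs 0.0118); and knocking out the master TF pushes resident cells
away from homeostasis (fitted topic k1, negative score) and toward
inflammation (fitted topic k3, positive score) — the planted architecture,
recovered by inference alone.

The same stages are scriptable from a shell:

```bash
amgrn simulate --outdir demo --seed 1
amgrn run-all --outdir demo_run --seed 1
```

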