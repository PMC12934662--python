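"""Synthetic single-cell data with planted topic, network and motif truth.

The generator emulates the statistical structure of an LPS-challenge
alveolar-macrophage experiment: two populations sampled over a timecourse,
where the tissue-resident-like population carries a densely interconnected
TF-TF regulatory core and stays close to a homeostatic expression program,
while the recruited-like population has a sparse TF-TF core and swings
strongly into an inflammatory program at the early timepoint.

Counts follow a grade-of-membership model: each cell mixes K topic-specific
gene distributions, TF log-rates receive Gaussian noise plus TF-TF network
coupling, target-gene log-rates receive signed linear effects of the
standardized regulator rates, and counts are drawn multinomially at a
Poisson-distributed library size.  Every planted quantity (topic
distributions, per-cell proportions, signed network edges, motif placements)
is recorded in a :class:`GroundTruth` ledger so downstream inference can be
scored against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import ConfigError, CountMatrix, GenerationError, stage_rng, zscore_columns
from .motifs import PWM, reverse_complement, scan_pwms

logger = logging.getLogger("amgrn")

RESIDENT = "resident-like"
RECRUITED = "recruited-like"
POPULATIONS = (RESIDENT, RECRUITED)

# Sequence layout: one short contig per gene, a single accessible peak, and
# the TSS downstream of the peak.  Motifs are planted centered in the peak.
CONTIG_LEN = 300
PEAK_START, PEAK_END = 40, 240
TSS_POS = 260
MOTIF_LEN = 8
MOTIF_GAP = 4


@dataclass
class SyntheticConfig:
    """Generator settings.

    Defaults describe the emulated study conditions: two populations of
    2,000 cells across four timepoints, 500 genes of which 20 are TFs,
    three functional topics, and a dense (0.30) versus sparse (0.05)
    directed TF-TF edge density contrast.  ``tf_activity_sd`` is the
    cell-to-cell fluctuation of TF activity that drives regulatory
    coupling; ``noise_sd`` is observation noise added to every gene's
    log-rate after coupling; ``edge_weight_scale`` multiplies all planted
    regulatory weights.
    """

    n_cells_per_population: int = 2000
    n_genes: int = 500
    n_tfs: int = 20
    n_topics_true: int = 3
    timepoints: tuple = ("d0", "d3", "d6", "d15")
    library_size_mean: int = 5000
    tf_tf_density_dense: float = 0.30
    tf_tf_density_sparse: float = 0.05
    edge_weight_scale: float = 0.6
    noise_sd: float = 0.2
    seed: int = 0
    # secondary knobs (fixed aspects of the emulated design)
    tf_activity_sd: float = 0.3
    tf_mass_share: float = 0.15
    n_targets_per_tf: int = 25
    n_master_targets: int = 40
    n_decoy_sites_per_tf: int = 15
    n_marker_genes: int = 8
    dirichlet_concentration: float = 30.0
    tf_topic_sd: float = 0.1

    def validate(self):
        counts = dict(
            n_cells_per_population=self.n_cells_per_population,
            n_genes=self.n_genes, n_tfs=self.n_tfs,
            n_topics_true=self.n_topics_true,
            library_size_mean=self.library_size_mean,
        )
        for name, v in counts.items():
            if int(v) < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        for name in ("tf_tf_density_dense", "tf_tf_density_sparse"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.tf_tf_density_dense <= self.tf_tf_density_sparse:
            raise ConfigError("tf_tf_density_dense must exceed tf_tf_density_sparse")
        if self.n_tfs >= self.n_genes:
            raise ConfigError(f"n_tfs ({self.n_tfs}) must be < n_genes ({self.n_genes})")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(self.timepoints) < 1:
            raise ConfigError("at least one timepoint required")


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted."""

    topic_names: list[str]
    topic_gene_dists: pd.DataFrame        # genes x K, columns sum to 1
    cell_topic_props: pd.DataFrame        # cells x K, rows sum to 1
    grn_edges: pd.DataFrame               # population, regulator, target, weight
    population_labels: pd.Series          # per cell
    cell_meta: pd.DataFrame               # population, timepoint per cell
    planted_motifs: pd.DataFrame          # motif, peak, gene, topic, is_decoy
    motif_consensus: dict
    motif_to_tf: dict
    master_tf: dict                       # population -> TF id
    marker_genes: dict                    # population -> marker gene ids
    topic_signature_genes: dict           # topic name -> gene ids
    tf_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        F = self.topic_gene_dists.to_numpy()
        if not np.allclose(F.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("topic gene distributions must sum to 1")
        P = self.cell_topic_props.to_numpy()
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("cell topic proportions must sum to 1")
        tfs = set(self.tf_ids)
        if not set(self.grn_edges["regulator"]).issubset(tfs):
            raise ValueError("every GRN regulator must be a TF")
        if (self.grn_edges["regulator"] == self.grn_edges["target"]).any():
            raise ValueError("self-edges are not allowed")

    def edges_for(self, population: str) -> pd.DataFrame:
        return self.grn_edges[self.grn_edges["population"] == population]


def _topic_names(K: int) -> list[str]:
    base = ["homeostasis", "inflammation", "resolution"]
    if K <= 3:
        return base[:K]
    return base + [f"topic{k}" for k in range(3, K)]


def _mean_topic_props(population: str, tp_index: int, K: int) -> np.ndarray:
    """Population x timepoint mean topic proportions.

    The recruited-like population shifts hard into inflammation at the
    second timepoint and into resolution at the third; the resident-like
    population shows only a weak inflammation bump and stays predominantly
    homeostatic throughout.
    """
    res = [(0.80, 0.10, 0.10), (0.60, 0.25, 0.15),
           (0.65, 0.15, 0.20), (0.80, 0.10, 0.10)]
    rec = [(0.55, 0.25, 0.20), (0.15, 0.70, 0.15),
           (0.25, 0.25, 0.50), (0.50, 0.25, 0.25)]
    base = (res if population == RESIDENT else rec)[min(tp_index, 3)]
    if K == 1:
        return np.array([1.0])
    if K == 2:
        v = np.array([base[0] + base[2], base[1]])
        return v / v.sum()
    v = np.array(list(base) + [0.02] * (K - 3))
    return v / v.sum()


def _draw_signed_weights(rng, n, scale, lo=0.2, hi=1.0):
    mag = rng.uniform(lo, hi, n) * scale
    sign = rng.choice([-1.0, 1.0], n)
    return mag * sign


def _random_consensus(rng, existing: set) -> str:
    """Random motif consensus, distinct from existing motifs and their
    reverse complements, and not its own reverse complement."""
    bases = "ACGT"
    while True:
        s = "".join(bases[i] for i in rng.integers(0, 4, MOTIF_LEN))
        rc = reverse_complement(s)
        if s != rc and s not in existing and rc not in existing:
            return s


def generate_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Plant topics, per-cell proportions, population-specific networks,
    marker genes and motif placements.  Deterministic given ``config.seed``."""
    config.validate()
    rng = stage_rng(config.seed, "truth")
    K = config.n_topics_true
    n_tfs, n_genes = config.n_tfs, config.n_genes
    tf_ids = [f"TF{i:02d}" for i in range(n_tfs)]
    other_ids = [f"G{i:04d}" for i in range(n_tfs, n_genes)]
    gene_ids = tf_ids + other_ids
    n_other = len(other_ids)
    topic_names = _topic_names(K)

    # --- topic gene distributions: per-topic signature blocks over non-TF
    # genes, TFs carry a fixed share of total mass with mild per-topic tilt.
    sig_size = max(1, n_other // (K + 2))
    signature = {
        topic_names[k]: other_ids[k * sig_size:(k + 1) * sig_size] for k in range(K)
    }
    tf_share = config.tf_mass_share
    F = np.zeros((n_genes, K))
    for k in range(K):
        w = rng.gamma(2.0, 1.0, n_other) + 1e-3
        w[k * sig_size:(k + 1) * sig_size] *= 8.0
        w = w / w.sum() * (1.0 - tf_share)
        tfw = np.exp(rng.normal(0.0, config.tf_topic_sd, n_tfs))
        if k == 0 and K >= 2:
            # the homeostasis master TF is itself a homeostasis-topic gene,
            # so its activity varies along the homeostasis axis rather than
            # forming an orthogonal factor of its own
            tfw[0] *= 4.0
        tfw = tfw / tfw.sum() * tf_share
        F[:n_tfs, k] = tfw
        F[n_tfs:, k] = w
    F = F / F.sum(axis=0, keepdims=True)
    topic_gene_dists = pd.DataFrame(F, index=pd.Index(gene_ids, name="gene"),
                                    columns=topic_names)

    # --- cells: populations split evenly across timepoints
    timepoints = list(config.timepoints)
    n_pc = config.n_cells_per_population
    cell_rows = []
    for pop, tag in ((RESIDENT, "res"), (RECRUITED, "rec")):
        for i in range(n_pc):
            t_idx = i % len(timepoints)
            cell_rows.append((f"{tag}_{timepoints[t_idx]}_{i:05d}", pop,
                              timepoints[t_idx], t_idx))
    cell_meta = pd.DataFrame(cell_rows, columns=["cell", "population",
                                                 "timepoint", "_t"]).set_index("cell")

    conc = config.dirichlet_concentration
    props = np.empty((len(cell_meta), K))
    for pop in POPULATIONS:
        for t_idx in range(len(timepoints)):
            sel = np.flatnonzero((cell_meta["population"] == pop)
                                 & (cell_meta["_t"] == t_idx))
            alpha = np.maximum(_mean_topic_props(pop, t_idx, K) * conc, 0.05)
            props[sel] = rng.dirichlet(alpha, len(sel))
    cell_topic_props = pd.DataFrame(props, index=cell_meta.index, columns=topic_names)
    cell_meta = cell_meta.drop(columns="_t")

    # --- TF-TF edges: dense core in the resident-like population, sparse in
    # the recruited-like population (directed, no self-edges).
    densities = {RESIDENT: config.tf_tf_density_dense,
                 RECRUITED: config.tf_tf_density_sparse}
    edge_rows = []
    for pop in POPULATIONS:
        mask = rng.random((n_tfs, n_tfs)) < densities[pop]
        np.fill_diagonal(mask, False)
        regs, tgts = np.nonzero(mask)
        weights = _draw_signed_weights(rng, len(regs), config.edge_weight_scale)
        for r, t, w in zip(regs, tgts, weights):
            edge_rows.append((pop, tf_ids[r], tf_ids[t], float(w)))

    # --- TF -> gene edges shared between populations (the density contrast
    # is confined to the TF-TF core); the master TF is handled separately.
    shared_rows = []
    for i, tf in enumerate(tf_ids):
        if i == 0 and K >= 2:
            continue  # master TF
        targets = rng.choice(other_ids, size=min(config.n_targets_per_tf, n_other),
                             replace=False)
        weights = _draw_signed_weights(rng, len(targets), config.edge_weight_scale)
        shared_rows.extend((tf, t, float(w)) for t, w in zip(targets, weights))

    # --- master TF: positively drives a homeostasis-gene block and
    # represses an inflammation-gene block (signs fixed by construction).
    master_rows = []
    master_tf = {}
    if K >= 2:
        master = tf_ids[0]
        master_tf = {pop: master for pop in POPULATIONS}
        n_m = min(config.n_master_targets, sig_size)
        homeo_targets = signature[topic_names[0]][:n_m]
        inflam_targets = signature[topic_names[1]][:n_m]
        w_h = rng.uniform(0.35, 0.7, n_m) * config.edge_weight_scale
        w_i = -rng.uniform(0.35, 0.7, n_m) * config.edge_weight_scale
        master_rows.extend((master, t, float(w)) for t, w in zip(homeo_targets, w_h))
        master_rows.extend((master, t, float(w)) for t, w in zip(inflam_targets, w_i))

    for pop in POPULATIONS:
        edge_rows.extend((pop, r, t, w) for r, t, w in shared_rows + master_rows)
    grn_edges = (pd.DataFrame(edge_rows,
                              columns=["population", "regulator", "target", "weight"])
                 .drop_duplicates(subset=["population", "regulator", "target"])
                 .reset_index(drop=True))

    # --- population marker genes (constitutive, topic-independent), taken
    # from background genes outside every signature block.
    background = other_ids[K * sig_size:]
    n_mark = config.n_marker_genes
    if len(background) < 2 * n_mark:
        raise ConfigError("not enough background genes for population markers")
    if n_mark > 0:
        marker_genes = {RESIDENT: background[-2 * n_mark:-n_mark],
                        RECRUITED: background[-n_mark:]}
    else:
        marker_genes = {RESIDENT: [], RECRUITED: []}

    # --- motif catalog: one motif per TF planted in the peaks of its target
    # genes (union over populations) plus decoy placements near non-targets,
    # and two annotation-only motifs confined to one topic block each.
    consensus: dict[str, str] = {}
    motif_to_tf = {}
    for tf in tf_ids:
        mid = f"M_{tf}"
        consensus[mid] = _random_consensus(rng, set(consensus.values()))
        motif_to_tf[mid] = tf
    for mid in ("M_HOMEO", "M_INFLAM"):
        consensus[mid] = _random_consensus(rng, set(consensus.values()))

    gene_topic = {}
    for name, genes in signature.items():
        for g in genes:
            gene_topic[g] = name
    motif_rows = []
    for tf in tf_ids:
        mid = f"M_{tf}"
        targets = sorted(set(grn_edges.loc[grn_edges["regulator"] == tf, "target"]))
        for g in targets:
            motif_rows.append((mid, f"peak_{g}", g, gene_topic.get(g, ""), False))
        pool = [g for g in gene_ids if g not in targets and g != tf]
        decoys = rng.choice(pool, size=min(config.n_decoy_sites_per_tf, len(pool)),
                            replace=False)
        for g in decoys:
            motif_rows.append((mid, f"peak_{g}", g, gene_topic.get(g, ""), True))
    if K >= 2:
        for mid, topic in (("M_HOMEO", topic_names[0]), ("M_INFLAM", topic_names[1])):
            picks = rng.choice(signature[topic], size=min(12, sig_size), replace=False)
            for g in picks:
                motif_rows.append((mid, f"peak_{g}", g, topic, False))
    planted_motifs = (pd.DataFrame(motif_rows,
                                   columns=["motif", "peak", "gene", "topic", "is_decoy"])
                      .drop_duplicates(subset=["motif", "peak"])
                      .reset_index(drop=True))

    return GroundTruth(
        topic_names=topic_names,
        topic_gene_dists=topic_gene_dists,
        cell_topic_props=cell_topic_props,
        grn_edges=grn_edges,
        population_labels=cell_meta["population"].copy(),
        cell_meta=cell_meta,
        planted_motifs=planted_motifs,
        motif_consensus=consensus,
        motif_to_tf=motif_to_tf,
        master_tf=master_tf,
        marker_genes=marker_genes,
        topic_signature_genes=signature,
        tf_ids=tf_ids,
        gene_ids=gene_ids,
    )


def simulate_counts(truth: GroundTruth, config: SyntheticConfig) -> CountMatrix:
    """Draw multinomial counts from the planted generative model.

    Per cell the rate vector is the topic mixture.  TF log-rates receive a
    Gaussian activity fluctuation (``tf_activity_sd``) plus one pass of
    TF-TF network coupling; target genes receive the signed weighted sum of
    their regulators' standardized activities (standardized within
    population).  Coupling terms are mean-preserving on the rate scale
    (half their variance is subtracted on the log scale) so network effects
    perturb cells without biasing the topic gene distributions.  Gaussian
    observation noise (``noise_sd``) is then added to every gene's
    log-rate, rates are renormalized to a probability vector, and counts
    are drawn multinomially at a Poisson(library_size_mean) library size.
    """
    config.validate()
    rng = stage_rng(config.seed, "counts")
    gene_ids = truth.gene_ids
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    tf_pos = np.array([gene_pos[t] for t in truth.tf_ids])
    F = truth.topic_gene_dists.to_numpy()  # genes x K
    meta = truth.cell_meta
    n_genes = len(gene_ids)
    blocks = []
    order = []
    for pop in POPULATIONS:
        cells = meta.index[meta["population"] == pop]
        order.extend(cells)
        P = truth.cell_topic_props.loc[cells].to_numpy()
        n = len(cells)
        M = P @ F.T  # mixture rates, cells x genes
        lograte = np.log(M)
        # constitutive population markers
        for g in truth.marker_genes.get(pop, []):
            lograte[:, gene_pos[g]] += np.log(6.0)
        other = RECRUITED if pop == RESIDENT else RESIDENT
        for g in truth.marker_genes.get(other, []):
            lograte[:, gene_pos[g]] -= np.log(5.0)
        # TF activity fluctuation and TF-TF coupling (single pass over base
        # activities), then the gene-target coupling
        edges = truth.edges_for(pop)
        tf_index = {t: j for j, t in enumerate(truth.tf_ids)}
        A = lograte[:, tf_pos] + config.tf_activity_sd * rng.standard_normal(
            (n, len(tf_pos)))
        Z0, _, _ = zscore_columns(A)
        Wtf = np.zeros((len(truth.tf_ids), len(truth.tf_ids)))
        tftf = edges[edges["target"].isin(tf_index)]
        for _, e in tftf.iterrows():
            Wtf[tf_index[e["regulator"]], tf_index[e["target"]]] += e["weight"]
        Etf = Z0 @ Wtf
        # mean-preserving on the rate scale: exp of a centered Gaussian-ish
        # term has mean exp(var/2), so subtract half the empirical variance
        A += Etf - Etf.var(axis=0) / 2.0
        lograte[:, tf_pos] = A
        Z, _, _ = zscore_columns(A)
        gene_edges = edges[~edges["target"].isin(tf_index)]
        W = np.zeros((len(truth.tf_ids), n_genes))
        for _, e in gene_edges.iterrows():
            W[tf_index[e["regulator"]], gene_pos[e["target"]]] += e["weight"]
        E = Z @ W
        lograte += E - E.var(axis=0) / 2.0
        # observation noise on every gene, after the coupling
        lograte += config.noise_sd * rng.standard_normal((n, n_genes))
        bad = ~np.isfinite(lograte).all(axis=0)
        if bad.any():
            raise GenerationError(
                f"non-finite rate for gene {gene_ids[int(np.flatnonzero(bad)[0])]}"
            )
        rate = np.exp(lograte)
        p = rate / rate.sum(axis=1, keepdims=True)
        libs = np.maximum(rng.poisson(config.library_size_mean, n), 1)
        blocks.append(rng.multinomial(libs, p))
    counts = np.vstack(blocks)  # cells x genes, in `order`
    cm = CountMatrix(sp.csr_matrix(counts.T), gene_ids, list(order),
                     meta.loc[list(order)])
    return cm


@dataclass
class SequenceBundle:
    """Synthetic regulatory sequences with their interval annotations."""

    sequences: dict            # contig -> sequence
    peaks: pd.DataFrame        # contig, start, end, name
    tss: pd.DataFrame          # contig, start, end, name
    pwms: list                 # PWM objects
    placements: pd.DataFrame   # motif, contig, start, end, peak, gene

    def __iter__(self):
        return iter((self.sequences, self.peaks, self.tss, self.pwms))


def random_background(rng, length: int) -> str:
    """Uniform-composition i.i.d. ACGT background sequence."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def generate_regulatory_sequences(
    truth: GroundTruth,
    config: SyntheticConfig,
    scrub_spurious: bool = True,
    scan_threshold: float = 10.0,
) -> SequenceBundle:
    """One contig per gene with a single peak and the TSS downstream.

    Planted motif consensus sequences are embedded centered in the peak
    (several sites are laid out with small random gaps).  With
    ``scrub_spurious`` (the default) background bases are re-drawn until no
    catalog motif scores above ``scan_threshold`` anywhere outside a planted
    site, so the placement ledger is the complete set of scannable hits.
    """
    rng = stage_rng(config.seed, "sequences")
    pwms = [PWM.from_consensus(mid, cons) for mid, cons in truth.motif_consensus.items()]
    peak_len = PEAK_END - PEAK_START
    sequences, placement_rows = {}, []
    peak_rows, tss_rows = [], []
    by_gene = truth.planted_motifs.groupby("gene")
    for gene in truth.gene_ids:
        contig = f"ctg_{gene}"
        seq = np.frombuffer(random_background(rng, CONTIG_LEN).encode(), dtype="S1").copy()
        motifs_here = (sorted(by_gene.get_group(gene)["motif"])
                       if gene in by_gene.groups else [])
        block = len(motifs_here) * (MOTIF_LEN + MOTIF_GAP) - MOTIF_GAP
        if motifs_here and block > peak_len:
            raise GenerationError(
                f"{gene}: {len(motifs_here)} motif sites exceed the {peak_len} bp peak"
            )
        start0 = PEAK_START + (peak_len - block) // 2 if motifs_here else 0
        planted_ivals = []
        for i, mid in enumerate(motifs_here):
            s = start0 + i * (MOTIF_LEN + MOTIF_GAP)
            cons = truth.motif_consensus[mid]
            seq[s:s + MOTIF_LEN] = np.frombuffer(cons.encode(), dtype="S1")
            planted_ivals.append((mid, s, s + MOTIF_LEN))
            placement_rows.append((mid, contig, s, s + MOTIF_LEN,
                                   f"peak_{gene}", gene))
        sequences[contig] = seq.tobytes().decode()
        peak_rows.append((contig, PEAK_START, PEAK_END, f"peak_{gene}"))
        tss_rows.append((contig, TSS_POS, TSS_POS + 1, gene))
        if scrub_spurious:
            # scrub slightly below the scan threshold so downstream scans with
            # a background estimated from the sequences stay hit-free too
            sequences[contig] = _scrub_contig(
                rng, sequences[contig], pwms, planted_ivals,
                scan_threshold - 0.5, contig
            )
    peaks = pd.DataFrame(peak_rows, columns=["contig", "start", "end", "name"])
    tss = pd.DataFrame(tss_rows, columns=["contig", "start", "end", "name"])
    placements = pd.DataFrame(
        placement_rows, columns=["motif", "contig", "start", "end", "peak", "gene"]
    )
    return SequenceBundle(sequences, peaks, tss, pwms, placements)


def _scrub_contig(rng, seq, pwms, planted_ivals, threshold, contig,
                  max_rounds: int = 60) -> str:
    """Re-draw background bases until no unplanted site reaches threshold."""
    planted = {(m, s, e) for m, s, e in planted_ivals}
    protected = np.zeros(len(seq), dtype=bool)
    for _, s, e in planted_ivals:
        protected[s:e] = True
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for _ in range(max_rounds):
        hits = scan_pwms({contig: arr.tobytes().decode()}, pwms,
                         threshold=threshold, background="uniform")
        spurious = [h for h in hits
                    if not (h.strand == "+" and (h.motif_id, h.start, h.end) in planted)]
        if not spurious:
            return arr.tobytes().decode()
        for h in spurious:
            free = np.arange(h.start, h.end)[~protected[h.start:h.end]]
            if len(free) == 0:
                raise GenerationError(
                    f"{contig}: spurious hit {h.motif_id} entirely inside planted bases"
                )
            draws = rng.integers(0, 4, len(free))
            for j, b in zip(free, draws):
                arr[j] = "ACGT"[b].encode()
    raise GenerationError(f"{contig}: could not scrub spurious motif hits")


def make_base_grn_with_decoys(truth: GroundTruth):
    """Candidate edge set implied by the planted motif placements.

    Equivalent to running the motif-scanning route on the synthetic
    sequences: all true TF -> target edges (union over populations) plus the
    planted decoy sites, as a BaseGRN.
    """
    from .grn import BaseGRN

    pm = truth.planted_motifs
    pm = pm[pm["motif"].isin(truth.motif_to_tf)].copy()
    pm["regulator"] = pm["motif"].map(truth.motif_to_tf)
    edges = pm.rename(columns={"gene": "target"})
    edges = edges[edges["regulator"] != edges["target"]]
    edges = (edges[["regulator", "target", "motif", "peak"]]
             .drop_duplicates(subset=["regulator", "target"])
             .sort_values(["regulator", "target"]).reset_index(drop=True))
    return BaseGRN(edges)


def write_ground_truth(truth: GroundTruth, outdir):
    from .io import write_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.topic_gene_dists.to_csv(outdir / "topic_gene_dists.tsv", sep="\t")
    truth.cell_topic_props.to_csv(outdir / "cell_topic_props.tsv", sep="\t")
    truth.grn_edges.to_csv(outdir / "grn_edges.tsv", sep="\t", index=False)
    truth.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    truth.planted_motifs.to_csv(outdir / "planted_motifs.tsv", sep="\t", index=False)
    write_json(
        {
            "topic_names": truth.topic_names,
            "motif_consensus": truth.motif_consensus,
            "motif_to_tf": truth.motif_to_tf,
            "master_tf": truth.master_tf,
            "marker_genes": truth.marker_genes,
            "topic_signature_genes": truth.topic_signature_genes,
            "tf_ids": truth.tf_ids,
            "gene_ids": truth.gene_ids,
        },
        outdir / "truth.json",
    )
    return outdir


def read_ground_truth(indir) -> GroundTruth:
    from .io import read_json

    indir = Path(indir)
    meta = read_json(indir / "truth.json")
    cell_meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col=0)
    return GroundTruth(
        topic_names=meta["topic_names"],
        topic_gene_dists=pd.read_csv(indir / "topic_gene_dists.tsv", sep="\t", index_col=0),
        cell_topic_props=pd.read_csv(indir / "cell_topic_props.tsv", sep="\t", index_col=0),
        grn_edges=pd.read_csv(indir / "grn_edges.tsv", sep="\t"),
        population_labels=cell_meta["population"],
        cell_meta=cell_meta,
        planted_motifs=pd.read_csv(indir / "planted_motifs.tsv", sep="\t",
                                   keep_default_na=False),
        motif_consensus=meta["motif_consensus"],
        motif_to_tf=meta["motif_to_tf"],
        master_tf=meta["master_tf"],
        marker_genes=meta["marker_genes"],
        topic_signature_genes=meta["topic_signature_genes"],
        tf_ids=meta["tf_ids"],
        gene_ids=meta["gene_ids"],
    )
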