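"""PWM motif scanning and motif-based candidate network construction.

A PWM is stored as a 4 x L position-frequency matrix (rows A, C, G, T).
Scanning scores every offset on both strands with a summed log2 odds ratio
against a background base composition, keeps hits at or above a threshold,
and resolves same-strand overlaps in favour of the higher score.  Hits in
accessible peaks near gene transcription start sites become candidate
TF -> target edges (the "base GRN") that the regression stage is allowed
to fit; a wider window supports per-topic motif enrichment counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParseError

logger = logging.getLogger("amgrn")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on encoded bases


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGT (case-insensitive) to int8 0..3; other codes become -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq.upper()))


@dataclass
class PWM:
    """Position-frequency matrix with derived log-odds scoring.

    ``pfm`` holds non-negative counts or frequencies, shape 4 x L with rows
    in A, C, G, T order.  A pseudocount is added to the column-normalized
    frequencies before taking log2 odds against the background.
    """

    motif_id: str
    pfm: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: PFM must be 4 x L")
        if self.pfm.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if (self.pfm < 0).any():
            raise ValueError(f"{self.motif_id}: negative PFM entries")
        if (self.pfm.sum(axis=0) == 0).any():
            raise ValueError(f"{self.motif_id}: empty PFM column")

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    def frequencies(self) -> np.ndarray:
        """Column-stochastic frequencies after pseudocount regularization."""
        f = self.pfm / self.pfm.sum(axis=0, keepdims=True)
        f = f + self.pseudocount
        return f / f.sum(axis=0, keepdims=True)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = _as_background(background)
        return np.log2(self.frequencies() / bg[:, None])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.pfm, axis=0))

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=0).sum())

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str,
                       dominance: float = 997.0) -> "PWM":
        """Sharp PWM concentrated on a consensus (count `dominance` vs 1)."""
        L = len(consensus)
        pfm = np.ones((4, L))
        for j, b in enumerate(consensus.upper()):
            pfm[BASE_INDEX[b], j] = dominance
        return cls(motif_id, pfm)


@dataclass
class MotifHit:
    """One scored motif occurrence (0-based half-open interval)."""

    motif_id: str
    contig: str
    start: int
    end: int
    strand: str
    score: float


def _as_background(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    return bg / bg.sum()


def estimate_background(sequences: dict[str, str]) -> np.ndarray:
    """Strand-symmetrized ACGT composition of the supplied sequences."""
    counts = np.zeros(4)
    for seq in sequences.values():
        enc = encode_sequence(seq)
        enc = enc[enc >= 0]
        counts += np.bincount(enc, minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    sym = (counts + counts[_COMPLEMENT]) / 2.0
    return sym / sym.sum()


def _resolve_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Within (contig, strand), drop hits overlapping a higher-scoring hit."""
    kept: list[MotifHit] = []
    by_key: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig, h.strand), []).append(h)
    for group in by_key.values():
        group = sorted(group, key=lambda h: (-h.score, h.start))
        chosen: list[MotifHit] = []
        for h in group:
            if all(h.end <= c.start or h.start >= c.end for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.contig, h.start, h.strand))
    return kept


def scan_pwm(
    sequences: dict[str, str],
    pwm: PWM,
    threshold: float = 10.0,
    background: np.ndarray | str | None = "estimate",
    resolve_overlaps: bool = True,
) -> list[MotifHit]:
    """Scan both strands of every sequence; report hits scoring >= threshold.

    ``background`` may be "estimate" (composition of the supplied sequences,
    strand-symmetrized), "uniform"/None, or an explicit length-4 frequency
    vector.  Positions containing ambiguity codes are skipped with a warning.
    Overlapping same-strand hits keep only the higher score (ties broken by
    position; disable with ``resolve_overlaps=False`` for the raw hit set).
    """
    if isinstance(background, str):
        if background == "estimate":
            bg = estimate_background(sequences)
        elif background == "uniform":
            bg = np.full(4, 0.25)
        else:
            raise ValueError(f"unknown background mode {background!r}")
    else:
        bg = _as_background(background)

    lom = pwm.log_odds(bg)  # 4 x L
    # Reverse-strand scoring reuses the forward window: score of the reverse
    # complement equals scanning with the complemented, position-reversed matrix.
    lom_rc = lom[_COMPLEMENT][:, ::-1]
    L = pwm.length
    hits: list[MotifHit] = []
    warned = False
    for contig, seq in sequences.items():
        enc = encode_sequence(seq)
        if len(enc) < L:
            continue
        if (enc < 0).any() and not warned:
            logger.warning("ambiguity codes present; affected windows skipped")
            warned = True
        win = np.lib.stride_tricks.sliding_window_view(enc, L)  # n_off x L
        valid = (win >= 0).all(axis=1)
        pos = np.arange(L)
        safe = np.where(win >= 0, win, 0)
        fwd = lom[safe, pos].sum(axis=1)
        rev = lom_rc[safe, pos].sum(axis=1)
        for strand, scores in (("+", fwd), ("-", rev)):
            for off in np.flatnonzero(valid & (scores >= threshold)):
                hits.append(
                    MotifHit(pwm.motif_id, contig, int(off), int(off) + L,
                             strand, float(scores[off]))
                )
    return _resolve_overlaps(hits) if resolve_overlaps else hits


def scan_pwms(sequences, pwms, threshold=10.0, background="estimate"):
    """Scan a collection of PWMs; concatenated hit list."""
    out: list[MotifHit] = []
    for p in pwms:
        out.extend(scan_pwm(sequences, p, threshold=threshold, background=background))
    return out


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.motif_id, h.contig, h.start, h.end, h.strand, h.score) for h in hits],
        columns=["motif", "contig", "start", "end", "strand", "score"],
    )


def _check_intervals(df: pd.DataFrame, what: str):
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ParseError(f"{what}: malformed interval (start >= end) at line {bad[0] + 1}")


def assign_peaks_to_genes(
    peaks: pd.DataFrame, tss: pd.DataFrame, window_bp: int
) -> pd.DataFrame:
    """Map peaks to genes whose TSS lies within ``window_bp`` of the peak edge.

    ``peaks`` needs columns (contig, start, end, name); ``tss`` needs
    (contig, start, end, name) with the TSS at ``start`` (1 bp interval).
    Distance is measured from the closest covered base of the peak to the
    TSS position, 0 when the peak overlaps the TSS.  A peak may map to
    several genes.
    """
    peaks = peaks.reset_index(drop=True)
    tss = tss.reset_index(drop=True)
    _check_intervals(peaks, "peaks")
    _check_intervals(tss, "tss")
    rows = []
    tss_by_contig = {c: g for c, g in tss.groupby("contig")}
    for _, p in peaks.iterrows():
        cand = tss_by_contig.get(p["contig"])
        if cand is None:
            continue
        for _, t in cand.iterrows():
            tpos = int(t["start"])
            if p["start"] <= tpos < p["end"]:
                d = 0
            elif p["end"] <= tpos:
                d = tpos - (int(p["end"]) - 1)
            else:
                d = int(p["start"]) - tpos
            if d <= window_bp:
                rows.append((p["name"], t["name"], d, f"{window_bp}bp"))
    return pd.DataFrame(rows, columns=["peak", "gene", "distance", "window"])


def _hits_in_peaks(hits_df: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Annotate each hit with the peak(s) it overlaps."""
    rows = []
    peaks_by_contig = {c: g for c, g in peaks.groupby("contig")}
    for i, h in hits_df.iterrows():
        cand = peaks_by_contig.get(h["contig"])
        if cand is None:
            continue
        for _, p in cand.iterrows():
            if h["start"] < p["end"] and p["start"] < h["end"]:
                rows.append({**h.to_dict(), "peak": p["name"], "hit_id": i})
    return pd.DataFrame(rows)


def build_base_grn(
    hits: list[MotifHit] | pd.DataFrame,
    peak_gene_map: pd.DataFrame,
    motif_to_tf: dict[str, str],
    peaks: pd.DataFrame | None = None,
):
    """Candidate TF -> target edges from motif hits in peaks near genes.

    Each (hit-in-peak, peak -> gene) pair yields one candidate edge for the
    hit's TF, deduplicated with motif/peak provenance retained.  Hits whose
    motif has no TF mapping, and self-edges (a TF's motif in its own
    regulatory region), are dropped with a log message.
    """
    from .grn import BaseGRN

    hits_df = hits if isinstance(hits, pd.DataFrame) else hits_to_frame(hits)
    if peaks is not None and len(hits_df):
        hits_df = _hits_in_peaks(hits_df, peaks)
    if "peak" not in hits_df.columns:
        raise ValueError("hits need a 'peak' column or an explicit peaks table")
    unmapped = hits_df.loc[~hits_df["motif"].isin(motif_to_tf), "motif"].unique()
    if len(unmapped):
        logger.info("dropping %d motifs without a TF mapping: %s",
                    len(unmapped), ", ".join(sorted(unmapped)[:5]))
    hits_df = hits_df[hits_df["motif"].isin(motif_to_tf)].copy()
    hits_df["regulator"] = hits_df["motif"].map(motif_to_tf)
    merged = hits_df.merge(peak_gene_map[["peak", "gene"]], on="peak", how="inner")
    merged = merged.rename(columns={"gene": "target"})
    n_self = int((merged["regulator"] == merged["target"]).sum())
    if n_self:
        logger.info("dropping %d self-edges from base GRN", n_self)
    merged = merged[merged["regulator"] != merged["target"]]
    edges = (
        merged[["regulator", "target", "motif", "peak"]]
        .drop_duplicates(subset=["regulator", "target"])
        .sort_values(["regulator", "target"])
        .reset_index(drop=True)
    )
    return BaseGRN(edges)


def motif_topic_contrast(
    hits: list[MotifHit] | pd.DataFrame,
    peak_gene_map: pd.DataFrame,
    topic_gene_sets: dict[str, set],
    peaks: pd.DataFrame | None = None,
    motif_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-motif counts of distinct (hit, gene) assignments in each topic set.

    The analog of contrasting motif occurrences near genes of two functional
    programs: rows are motifs, columns are ``count_<set>`` for each named
    gene set, sorted by total count descending.  ``motif_ids`` may name the
    full motif catalog so motifs without hits appear with zero counts.
    """
    names = list(topic_gene_sets)
    overlap = set.intersection(*(set(s) for s in topic_gene_sets.values())) if len(names) > 1 else set()
    if overlap:
        logger.info("topic gene sets share %d genes", len(overlap))
    hits_df = hits if isinstance(hits, pd.DataFrame) else hits_to_frame(hits)
    if peaks is not None and len(hits_df):
        hits_df = _hits_in_peaks(hits_df, peaks)
    if len(hits_df) and "peak" not in hits_df.columns:
        raise ValueError("hits need a 'peak' column or an explicit peaks table")
    if len(hits_df) == 0:
        merged = pd.DataFrame(columns=["motif", "hit_id", "gene"])
    else:
        if "hit_id" not in hits_df.columns:
            hits_df = hits_df.reset_index(names="hit_id")
        merged = hits_df.merge(peak_gene_map[["peak", "gene"]], on="peak", how="inner")
    seen = sorted(set(hits_df["motif"])) if len(hits_df) else []
    all_motifs = sorted(set(seen) | set(motif_ids or []))
    rows = []
    for m in all_motifs:
        sub = merged[merged["motif"] == m].drop_duplicates(subset=["hit_id", "gene"])
        counts = {
            f"count_{name}": int(sub["gene"].isin(topic_gene_sets[name]).sum())
            for name in names
        }
        rows.append({"motif": m, **counts})
    out = pd.DataFrame(rows, columns=["motif"] + [f"count_{n}" for n in names])
    if len(out):
        out["total"] = out[[f"count_{n}" for n in names]].sum(axis=1)
        out = out.sort_values("total", ascending=False).reset_index(drop=True)
    return out
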