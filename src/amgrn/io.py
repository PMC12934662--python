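"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as a 10x-style MatrixMarket triplet plus a cell-metadata TSV;
sequences as FASTA; intervals as BED (0-based half-open); PWMs as 4-row
count tables; gene sets as GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CountMatrix, ParseError
from .motifs import PWM

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def write_counts_bundle(cm: CountMatrix, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(cm.counts))
    pd.Series(cm.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                  index=False, header=False)
    pd.Series(cm.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                  index=False, header=False)
    cm.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    return outdir


def read_counts_bundle(indir) -> CountMatrix:
    indir = Path(indir)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    meta_path = indir / "cell_meta.tsv"
    meta = pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
    return CountMatrix(counts, genes, cells, meta)


def write_fasta(sequences: dict[str, str], path):
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path):
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {i}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}: line {i}: start >= end")
            row = {"contig": parts[0], "start": start, "end": end}
            for j, col in enumerate(BED_COLUMNS[3:], start=3):
                if len(parts) > j:
                    row[col] = parts[j]
            rows.append(row)
    return pd.DataFrame(rows)


def write_pwms(pwms: list[PWM], path):
    """4-row count table per motif, preceded by a `>motif_id` header line."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\n")
            for b, row in zip("ACGT", p.pfm):
                fh.write(b + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def read_pwms(path) -> list[PWM]:
    """Read 4-row PWM tables; rows may or may not carry an A/C/G/T prefix."""
    pwms, name, rows = [], None, []
    def flush():
        if name is not None:
            if len(rows) != 4:
                raise ParseError(f"{path}: motif {name}: expected 4 rows, got {len(rows)}")
            pwms.append(PWM(name, np.array(rows)))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
            else:
                parts = line.replace(":", " ").split()
                if parts and parts[0].upper() in "ACGT" and len(parts[0]) == 1:
                    parts = parts[1:]
                rows.append([float(v) for v in parts])
    flush()
    return pwms


def read_gmt(path) -> dict[str, set]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: dict[str, set], path, description: str = "."):
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
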