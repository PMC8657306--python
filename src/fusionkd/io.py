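"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA/FASTQ handling is delegated to Biopython; tables go through pandas.
All readers are gzip-transparent where that makes sense (FASTQ).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import Exon, GeneModel


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path, records) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, sequence)`` pairs, order preserved."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq(path, reads) -> None:
    """Write ``(read_id, sequence)`` pairs as FASTQ with flat quality."""
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read FASTQ (optionally gzipped) into ``(id, sequence)`` pairs.

    Quality strings are parsed but discarded: no step downstream is
    quality-aware.
    """
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


# ---------------------------------------------------------------------------
# Annotation

def read_exon_table(path) -> list[GeneModel]:
    """Read a tab-separated exon table into gene models.

    Columns: gene_id, transcript_id, exon_index, exon_sequence.  Exons may
    appear in any order; they are sorted by index per transcript.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    required = {"gene_id", "transcript_id", "exon_index", "exon_sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exon table {path} is missing columns {sorted(missing)}")
    genes = []
    for (gene_id, transcript_id), grp in df.groupby(
        ["gene_id", "transcript_id"], sort=False
    ):
        grp = grp.sort_values("exon_index")
        exons = tuple(
            Exon(int(row.exon_index), str(row.exon_sequence).upper())
            for row in grp.itertuples()
        )
        genes.append(GeneModel(gene_id, transcript_id, exons))
    return genes


def write_exon_table(path, genes) -> None:
    rows = [
        (g.gene_id, g.transcript_id, e.index, e.sequence)
        for g in genes
        for e in g.exons
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "exon_index", "exon_sequence"]
    ).to_csv(path, sep="\t", index=False)


def read_gtf_like(gtf_path, fasta_path) -> list[GeneModel]:
    """Read a minimal GTF-like exon listing plus a companion exon FASTA.

    The GTF-like file is tab-separated with columns gene_id, transcript_id,
    exon_number; sequences come from the FASTA keyed
    ``<transcript_id>|exon<exon_number>``.
    """
    df = pd.read_csv(gtf_path, sep="\t", dtype=str)
    required = {"gene_id", "transcript_id", "exon_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation {gtf_path} is missing columns {sorted(missing)}")
    seqs = dict(read_fasta(fasta_path))
    genes = []
    for (gene_id, transcript_id), grp in df.groupby(
        ["gene_id", "transcript_id"], sort=False
    ):
        exons = []
        for row in grp.itertuples():
            idx = int(row.exon_number)
            key = f"{transcript_id}|exon{idx}"
            if key not in seqs:
                raise ValueError(f"no sequence for {key!r} in {fasta_path}")
            exons.append(Exon(idx, seqs[key].upper()))
        exons.sort(key=lambda e: e.index)
        genes.append(GeneModel(gene_id, transcript_id, tuple(exons)))
    return genes


# ---------------------------------------------------------------------------
# Matrices and metadata

def write_matrix_tsv(path, df: pd.DataFrame) -> None:
    """Write a feature x sample matrix as TSV with a ``feature`` index column."""
    df.to_csv(path, sep="\t", index_label="feature")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def write_json(path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


def read_gene_list(path) -> list[str]:
    """Read a gene list, one symbol per line; blank lines and # comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
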