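"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are tab-separated. Genomic intervals use BED conventions
(0-based, half-open). FASTA goes through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DE_COLUMNS = ["gene_id", "biotype", "logFC", "logCPM", "fdr", "tumor_fpkm", "treated_fpkm"]
METH_COLUMNS = ["gene_id", "promoter_level", "gene_body_level"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
PEPTIDE_COLUMNS = ["gene_name", "protein_id", "length", "peptide_id", "peptide_seq", "loc"]
EDGE_COLUMNS = ["node_a", "node_b", "score"]
READ_EVIDENCE_COLUMNS = ["read_id", "pseudogene_id", "maps_pseudogene", "maps_parent"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED6 file (no header, tab-separated)."""
    df[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if not bad.empty:
        raise ValueError(f"{path}: malformed interval at line {bad.index[0] + 1}")
    return df


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line -- name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
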