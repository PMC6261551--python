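"""Tumor-antigen peptide matching against protein sequences.

Two modes mirror how curated T-cell antigen exports are cross-referenced
with a proteome: *best match* reports every exact occurrence of a peptide in
a protein; *one-mismatch* additionally reports windows differing at exactly
one residue (substitutions only, equal length).  Locations are 1-based
starts of the matched window.  A downstream constraint step intersects the
matched genes with the differential profile: a gene survives when its logFC
is extreme (|logFC| beyond the up/down thresholds) and, where methylation
was measured, either the promoter or gene-body level passes its threshold;
genes with no methylation measurement pass on expression alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_BRACKET_RE = re.compile(r"\[([^\]]+)\]")
_PAREN_RE = re.compile(r"\(([A-Za-z])\)")


@dataclass(frozen=True)
class AntigenConstraint:
    """DiP thresholds restricting an antigen-matched gene list."""

    logfc_up: float = 1.5
    logfc_down: float = -1.5
    promoter_min: float = 2.9
    body_min: float = 8.39

    def __post_init__(self):
        if not self.logfc_down < self.logfc_up:
            raise ValueError("logfc_down must be below logfc_up")


def normalize_peptide(raw_seq: str) -> str:
    """Canonicalize a raw peptide string.

    Curated exports decorate variant peptides as ``QPR(S)PGPDYSL[QPRSPGPDYSL]``:
    the bracketed form, when present, is the canonical sequence; otherwise
    parentheses around single residues are stripped.  The result is
    uppercased and must use the 20-letter amino-acid alphabet.
    """
    m = _BRACKET_RE.search(raw_seq)
    seq = m.group(1) if m else _PAREN_RE.sub(r"\1", raw_seq)
    seq = seq.strip().upper()
    for ch in seq:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"non-amino-acid character {ch!r} in peptide {raw_seq!r}")
    return seq


def _hit_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["peptide_id", "protein_id", "loc",
                                       "n_mismatch", "mode"])


def match_exact(peptides: Mapping[str, str], proteins: Mapping[str, str]) -> pd.DataFrame:
    """All exact occurrences of each peptide in each protein (1-based loc)."""
    rows = []
    for pep_id, raw in peptides.items():
        pep = normalize_peptide(raw)
        for prot_id, prot in proteins.items():
            seq = prot.upper()
            start = seq.find(pep)
            while start != -1:
                rows.append((pep_id, prot_id, start + 1, 0, "best_match"))
                start = seq.find(pep, start + 1)
    return _hit_frame(rows)


def match_one_mismatch(peptides: Mapping[str, str],
                       proteins: Mapping[str, str]) -> pd.DataFrame:
    """All windows at Hamming distance <= 1 from each peptide.

    Substitutions only, equal length; exact occurrences appear with
    n_mismatch = 0, so the exact hit set is always contained in this one.
    A peptide longer than the protein simply yields no hits.
    """
    rows = []
    prot_arrays = {pid: np.frombuffer(p.upper().encode("ascii"), dtype=np.uint8)
                   for pid, p in proteins.items()}
    for pep_id, raw in peptides.items():
        pep = normalize_peptide(raw)
        pep_arr = np.frombuffer(pep.encode("ascii"), dtype=np.uint8)
        L = len(pep_arr)
        for prot_id, arr in prot_arrays.items():
            if arr.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mismatches = (windows != pep_arr).sum(axis=1)
            for off in np.flatnonzero(mismatches <= 1):
                rows.append((pep_id, prot_id, int(off) + 1,
                             int(mismatches[off]), "one_mismatch"))
    return _hit_frame(rows)


def peptides_from_table(peptide_table: pd.DataFrame) -> dict[str, str]:
    """peptide_id -> raw sequence from a curated-export-style table."""
    for col in ("peptide_id", "peptide_seq"):
        if col not in peptide_table.columns:
            raise ValueError(f"peptide table missing column {col!r}")
    return dict(zip(peptide_table["peptide_id"], peptide_table["peptide_seq"]))


def constrain_antigen_genes(hit_genes: set[str], dip_records: pd.DataFrame,
                            constraint: AntigenConstraint = AntigenConstraint()
                            ) -> list[str]:
    """Restrict antigen-matched genes by expression and methylation thresholds.

    ``dip_records`` needs gene_id, logFC, promoter_level, gene_body_level;
    NaN methylation means "not measured" and such genes are filtered on
    expression alone.
    """
    recs = dip_records.loc[dip_records["gene_id"].isin(hit_genes)]
    logfc = recs["logFC"]
    expr_ok = (logfc > constraint.logfc_up) | (logfc < constraint.logfc_down)
    has_meth = recs["promoter_level"].notna() | recs["gene_body_level"].notna()
    meth_ok = ((recs["promoter_level"] > constraint.promoter_min)
               | (recs["gene_body_level"] > constraint.body_min))
    keep = expr_ok & (~has_meth | meth_ok)
    return sorted(recs.loc[keep, "gene_id"].unique())
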