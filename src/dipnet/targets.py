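"""lincRNA cis-target assignment and pseudogene parental-gene assignment.

Targets: a protein-coding gene is a putative target of a lincRNA when its
interval intersects the lincRNA's locus extended by +/-1, 2 or 3 Mb
(half-open coordinates, strand-agnostic); among candidates, priority goes to
the nearest (boundary-to-boundary gap).  Regulation is *cis* when the pair is
on the same chromosome within the window, *trans* otherwise.

Parents: each pseudogene is assigned the candidate parent with the best
global-alignment score (the BLAST e-value stand-in: a fixed scoring scheme
gives the same argmax ordering).  Transcribed evidence follows two rules:
reads mapping to the pseudogene only (``unique_reads``), or reads shared
with the parent but sequence identity below 90%
(``shared_reads_low_identity``); anything else is ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

IDENTITY_CUTOFF = 0.90


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""
    feature_class: str = "gene"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.feature_id!r}: "
                f"[{self.start}, {self.end}) violates 0 <= start < end")


@dataclass
class TargetAssignment:
    ncrna_id: str
    target_gene_id: str
    window_mb: int
    gap_bp: int
    is_nearest: bool = False
    regulation_class: str = "cis"


@dataclass(frozen=True)
class ParentalAssignment:
    pseudogene_id: str
    parental_id: str
    identity: float
    best_hit_score: float
    evidence: str  # unique_reads | shared_reads_low_identity | none


def intervals_from_bed(bed: pd.DataFrame, feature_class_of=None) -> list[GenomicInterval]:
    """Build intervals from a BED6 frame; class inferred from the name prefix
    unless a callable is supplied."""
    out = []
    for row in bed.itertuples(index=False):
        if feature_class_of is not None:
            cls = feature_class_of(row.name)
        else:
            cls = "lincRNA" if str(row.name).startswith("LINC") else "gene"
        out.append(GenomicInterval(row.chrom, int(row.start), int(row.end),
                                   str(row.strand), str(row.name), cls))
    return out


def gap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Boundary-to-boundary distance; 0 iff the intervals intersect.

    Only defined on the same chromosome.
    """
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def find_window_targets(ncrna: GenomicInterval, genes: Sequence[GenomicInterval],
                        window_mb: int = 1) -> list[TargetAssignment]:
    """Genes whose interval intersects [start - w, end + w); sorted by gap
    then gene id."""
    w = int(window_mb * 1_000_000)
    lo, hi = ncrna.start - w, ncrna.end + w
    hits = []
    for g in genes:
        if g.chrom != ncrna.chrom:
            continue
        if g.start < hi and g.end > lo:  # half-open intersection
            hits.append(TargetAssignment(
                ncrna_id=ncrna.feature_id, target_gene_id=g.feature_id,
                window_mb=window_mb, gap_bp=gap_bp(ncrna, g)))
    hits.sort(key=lambda t: (t.gap_bp, t.target_gene_id))
    return hits


def find_all_window_targets(ncrnas: Sequence[GenomicInterval],
                            genes: Sequence[GenomicInterval],
                            windows_mb: Iterable[int] = (1, 2, 3)) -> list[TargetAssignment]:
    out = []
    for w in windows_mb:
        for nc in ncrnas:
            out.extend(find_window_targets(nc, genes, w))
    return out


def prioritize_nearest(assignments: list[TargetAssignment]) -> list[TargetAssignment]:
    """Flag exactly one nearest target per (ncRNA, window); ties break
    lexicographically by gene id."""
    by_key: dict[tuple[str, int], TargetAssignment] = {}
    for t in assignments:
        t.is_nearest = False
        key = (t.ncrna_id, t.window_mb)
        best = by_key.get(key)
        if best is None or (t.gap_bp, t.target_gene_id) < (best.gap_bp, best.target_gene_id):
            by_key[key] = t
    for t in by_key.values():
        t.is_nearest = True
    return assignments


def classify_regulation(ncrna: GenomicInterval, target: GenomicInterval,
                        window_mb: int = 1) -> str:
    """cis iff same chromosome and within the configured window, else trans."""
    if ncrna.chrom != target.chrom:
        return "trans"
    w = int(window_mb * 1_000_000)
    return "cis" if (target.start < ncrna.end + w and target.end > ncrna.start - w) \
        else "trans"


def assignments_to_frame(assignments: list[TargetAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.ncrna_id, t.target_gene_id, t.window_mb, t.gap_bp, t.is_nearest,
          t.regulation_class) for t in assignments],
        columns=["ncrna_id", "target_gene_id", "window_mb", "gap_bp",
                 "is_nearest", "regulation_class"])


# --- sequence identity and parental assignment ------------------------------

def _aligner(mismatch: float = 0.0, gap_open: float = -2.0,
             gap_extend: float = -0.5) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def pairwise_identity(seq_a: str, seq_b: str, mismatch: float = 0.0,
                      gap_open: float = -2.0, gap_extend: float = -0.5) -> float:
    """Global-alignment identity: matches / alignment length.

    Unit match score; mismatch and affine gap penalties configurable.
    Symmetric; equals 1.0 only for identical sequences.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    al = _aligner(mismatch, gap_open, gap_extend)
    aln = al.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    return counts.identities / aln.length


def alignment_score(seq_a: str, seq_b: str, mismatch: float = 0.0,
                    gap_open: float = -2.0, gap_extend: float = -0.5) -> float:
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    return float(_aligner(mismatch, gap_open, gap_extend).score(
        seq_a.upper(), seq_b.upper()))


def assign_parental(pseudogene_seqs: Mapping[str, str],
                    candidate_parent_seqs: Mapping[str, str],
                    read_overlap_table: pd.DataFrame) -> list[ParentalAssignment]:
    """Best-hit parent per pseudogene plus read-evidence classification.

    The parent is the argmax of the global alignment score over all
    candidates (ties broken by id).  Evidence uses the read table
    (columns read_id, pseudogene_id, maps_pseudogene, maps_parent):
    ``unique_reads`` when any read maps to the pseudogene only, else
    ``shared_reads_low_identity`` when shared reads exist and identity to the
    chosen parent is < 0.90, else ``none``.
    """
    if not candidate_parent_seqs:
        raise ValueError("need at least one candidate parent sequence")
    for col in ("read_id", "pseudogene_id", "maps_pseudogene", "maps_parent"):
        if col not in read_overlap_table.columns:
            raise ValueError(f"read-evidence table missing column {col!r}")
    out = []
    for pid in sorted(pseudogene_seqs):
        pseq = pseudogene_seqs[pid]
        if not pseq:
            raise ValueError(f"empty sequence for pseudogene {pid!r}")
        best_id, best_score = None, None
        for cid in sorted(candidate_parent_seqs):
            cseq = candidate_parent_seqs[cid]
            if not cseq:
                raise ValueError(f"missing/empty sequence for candidate {cid!r}")
            s = alignment_score(pseq, cseq)
            if best_score is None or s > best_score:
                best_id, best_score = cid, s
        identity = pairwise_identity(pseq, candidate_parent_seqs[best_id])
        reads = read_overlap_table.loc[read_overlap_table["pseudogene_id"] == pid]
        unique = bool(((reads["maps_pseudogene"] == 1)
                       & (reads["maps_parent"] == 0)).any())
        shared = bool(((reads["maps_pseudogene"] == 1)
                       & (reads["maps_parent"] == 1)).any())
        if unique:
            evidence = "unique_reads"
        elif shared and identity < IDENTITY_CUTOFF:
            evidence = "shared_reads_low_identity"
        else:
            evidence = "none"
        out.append(ParentalAssignment(pid, best_id, identity, best_score, evidence))
    return out
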