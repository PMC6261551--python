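"""Coupled differential profiles (DiP): joint expression/methylation filtering.

The central object is the per-gene join of a differential-expression record
(logFC, FDR, abundances) with a methylation record (promoter and gene-body
levels).  A gene counts as *re-activated* by the demethylating treatment when
its logFC exceeds the transcriptome threshold T and its promoter methylation
exceeds the methylome threshold M, both computed as quantiles (default the
50% quantile, i.e. the median) of the respective value distributions.  The
methylome threshold applies to the promoter level only; the gene-body level
is carried along and reported but does not gate the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_DE_REQUIRED = ["gene_id", "logFC", "fdr"]
_METH_REQUIRED = ["gene_id", "promoter_level", "gene_body_level"]


@dataclass(frozen=True)
class ThresholdSet:
    """Transcriptome (T) and methylome (M) thresholds at a quantile level."""

    t_expr: float
    m_meth: float
    quantile_level: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.quantile_level < 1.0:
            raise ValueError("quantile_level must lie in (0, 1)")


@dataclass(frozen=True)
class VennSummary:
    total_a: int
    specific_a: int
    total_b: int
    specific_b: int
    shared: int


def _require(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required column(s): {missing}")


def select_degs(de_table: pd.DataFrame, logfc_min: float = 1.0,
                fdr_max: float = 0.05) -> pd.DataFrame:
    """DEG call: keep rows with |logFC| > ``logfc_min`` and FDR < ``fdr_max``."""
    _require(de_table, _DE_REQUIRED, "DE")
    if not (np.isfinite(logfc_min) and np.isfinite(fdr_max)):
        raise ValueError("thresholds must be finite")
    keep = (de_table["logFC"].abs() > logfc_min) & (de_table["fdr"] < fdr_max)
    return de_table.loc[keep].reset_index(drop=True)


def compute_thresholds(values_expr: Iterable[float], values_meth: Iterable[float],
                       quantile_level: float = 0.5) -> ThresholdSet:
    """Quantile thresholds (linear interpolation between order statistics)."""
    expr = np.asarray(list(values_expr), dtype=float)
    meth = np.asarray(list(values_meth), dtype=float)
    if expr.size == 0 or meth.size == 0:
        raise ValueError("cannot compute a quantile of an empty value list")
    if not (np.isfinite(expr).all() and np.isfinite(meth).all()):
        raise ValueError("threshold inputs must be finite")
    return ThresholdSet(
        t_expr=float(np.quantile(expr, quantile_level)),
        m_meth=float(np.quantile(meth, quantile_level)),
        quantile_level=quantile_level,
    )


def compute_dip_thresholds(de_table: pd.DataFrame, meth_table: pd.DataFrame,
                           logfc_min: float = 1.0, fdr_max: float = 0.05,
                           quantile_level: float = 0.5) -> ThresholdSet:
    """T over upregulated DEGs' logFC, M over those genes' promoter levels.

    The reference analysis states only that both thresholds are 50% quantiles;
    the value population is a configuration choice and this default (the
    upregulated DEG set) follows the re-activation logic of the joint filter.
    """
    degs = select_degs(de_table, logfc_min, fdr_max)
    up = degs.loc[degs["logFC"] > 0]
    if up.empty:
        raise ValueError("no upregulated DEGs to compute thresholds over")
    joined = up.merge(meth_table, on="gene_id", how="inner")
    if joined.empty:
        raise ValueError("no upregulated DEG has a methylation record")
    return compute_thresholds(up["logFC"], joined["promoter_level"], quantile_level)


def apply_dip_filter(de_records: pd.DataFrame, meth_records: pd.DataFrame,
                     thresholds: ThresholdSet) -> pd.DataFrame:
    """Join DE and methylation records and flag threshold passes.

    Returns one row per DE gene with ``passes_expr`` (logFC > T),
    ``passes_meth`` (promoter > M, only meaningful when a methylation record
    exists), ``has_methylation`` and ``reactivated`` (both passes).  Genes
    with no methylation record are flagged, logged, and can never be
    re-activated.  Strict inequalities: ties at a threshold are excluded.
    """
    _require(de_records, _DE_REQUIRED, "DE")
    _require(meth_records, _METH_REQUIRED, "methylation")
    joined = de_records.merge(meth_records, on="gene_id", how="left")
    has_meth = joined["promoter_level"].notna() & joined["gene_body_level"].notna()
    n_missing = int((~has_meth).sum())
    if n_missing:
        logger.warning("%d DE gene(s) missing from the methylation table; "
                       "excluded from the re-activated set", n_missing)
    passes_expr = joined["logFC"] > thresholds.t_expr
    passes_meth = has_meth & (joined["promoter_level"] > thresholds.m_meth)
    out = joined.loc[:, ["gene_id", "logFC", "promoter_level", "gene_body_level"]].copy()
    out["passes_expr"] = passes_expr
    out["passes_meth"] = passes_meth
    out["has_methylation"] = has_meth
    out["reactivated"] = passes_expr & passes_meth
    return out


def reactivated_genes(dip_records: pd.DataFrame) -> set[str]:
    """The re-activated set: genes passing both T and M."""
    return set(dip_records.loc[dip_records["reactivated"], "gene_id"])


def venn_decompose(ids_a: set, ids_b: set) -> VennSummary:
    a, b = set(ids_a), set(ids_b)
    shared = len(a & b)
    return VennSummary(
        total_a=len(a), specific_a=len(a) - shared,
        total_b=len(b), specific_b=len(b) - shared,
        shared=shared,
    )


def biotype_decompose(de_records: pd.DataFrame) -> pd.Series:
    """Per-biotype counts; missing labels become 'NA'. Counts partition input."""
    if de_records.empty:
        return pd.Series(dtype=int, name="count")
    biotype = de_records.get("biotype")
    if biotype is None:
        biotype = pd.Series(["NA"] * len(de_records))
    labels = biotype.fillna("NA").replace("", "NA")
    counts = labels.value_counts().sort_index()
    counts.name = "count"
    return counts


def cross_reference(gene_ids: set[str], annotation_sets: Mapping[str, set[str]],
                    logfc: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Overlap of a gene list with each annotation set, with up/down split.

    ``logfc`` (gene -> logFC) is optional; without it the up/down columns are
    zero and only the overlap is reported.
    """
    rows = []
    for name, members in annotation_sets.items():
        overlap = sorted(gene_ids & set(members))
        n_up = n_down = 0
        if logfc is not None:
            n_up = sum(1 for g in overlap if logfc.get(g, 0.0) > 0)
            n_down = sum(1 for g in overlap if logfc.get(g, 0.0) < 0)
        rows.append((name, len(overlap), n_up, n_down, ",".join(overlap)))
    return pd.DataFrame(rows, columns=["set_name", "n_overlap", "n_up", "n_down",
                                       "overlap_genes"])


def enrich(gene_ids: set[str], universe: set[str],
           annotation_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation per set with BH correction.

    P(X >= k) for k = |query ∩ set| drawn n = |query| from N = |universe|
    containing K = |set ∩ universe| successes; q-values are Benjamini-
    Hochberg across the supplied sets.
    """
    outside = gene_ids - set(universe)
    if outside:
        raise ValueError(f"query gene(s) outside the universe: {sorted(outside)[:5]}")
    N, n = len(universe), len(gene_ids)
    names, pvals, ks, Ks = [], [], [], []
    for name, members in annotation_sets.items():
        K = len(set(members) & universe)
        k = len(gene_ids & set(members))
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        names.append(name); pvals.append(min(p, 1.0)); ks.append(k); Ks.append(K)
    if not names:
        return pd.DataFrame(columns=["set_name", "k", "K", "n", "N", "p", "q"])
    q = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "set_name": names, "k": ks, "K": Ks, "n": n, "N": N,
        "p": pvals, "q": q,
    }).sort_values("p", kind="stable").reset_index(drop=True)
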