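"""Linear model linking treated expression to promoter/gene-body methylation.

The question: after demethylating treatment, does the expression level of a
gene still reflect how methylated its promoter (or gene body) was?  Rows are
genes with a meaningful differential signal (|logFC| > 1.2 and some
methylation measured); treated expression (FPKM) and both methylation levels
are min-max normalized to [0, 1] over the selected rows, and ordinary least
squares fits

    treated ~ promoter + body

with two-sided t-tests per coefficient.  A negative, significant promoter
coefficient together with a null gene-body coefficient is the expected
silencing signature.  (A GLS fit with no correlation structure is identical
to OLS, so only OLS is implemented.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

_TERMS = ("intercept", "promoter", "body")


@dataclass(frozen=True)
class ModelFit:
    """OLS estimates for treated ~ promoter + body on normalized values."""

    beta_intercept: float
    beta_promoter: float
    beta_body: float
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    n: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "beta": {"intercept": self.beta_intercept,
                     "promoter": self.beta_promoter,
                     "body": self.beta_body},
            "se": self.se, "t": self.t, "p": self.p,
            "n": self.n, "r_squared": self.r_squared,
        }


def select_model_rows(de_records: pd.DataFrame, meth_records: pd.DataFrame,
                      logfc_min: float = 1.2) -> pd.DataFrame:
    """Join DE and methylation tables; keep |logFC| > logfc_min and any
    positive methylation (promoter or gene body)."""
    joined = de_records.merge(meth_records, on="gene_id", how="inner")
    keep = (joined["logFC"].abs() > logfc_min) & (
        (joined["promoter_level"] > 0) | (joined["gene_body_level"] > 0)
    )
    return joined.loc[keep].reset_index(drop=True)


def minmax_normalize(values) -> np.ndarray:
    """Affine map of a vector onto [0, 1]; rejects constant vectors."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = x.min(), x.max()
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("values must be finite")
    if hi == lo:
        raise ValueError("constant vector: min-max scaling undefined")
    return (x - lo) / (hi - lo)


def minmax_denormalize(norm, orig_min: float, orig_max: float) -> np.ndarray:
    return np.asarray(norm, dtype=float) * (orig_max - orig_min) + orig_min


def prepare_model_input(rows: pd.DataFrame) -> pd.DataFrame:
    """Normalize treated FPKM and the two methylation levels over the rows."""
    return pd.DataFrame({
        "gene_id": rows["gene_id"].to_numpy(),
        "treated_norm": minmax_normalize(rows["treated_fpkm"]),
        "promoter_norm": minmax_normalize(rows["promoter_level"]),
        "body_norm": minmax_normalize(rows["gene_body_level"]),
    })


def fit_linear_model(rows: pd.DataFrame) -> ModelFit:
    """OLS of treated_norm on promoter_norm + body_norm with intercept."""
    needed = ["treated_norm", "promoter_norm", "body_norm"]
    missing = [c for c in needed if c not in rows.columns]
    if missing:
        raise ValueError(f"model input missing column(s): {missing}")
    n = len(rows)
    if n <= 3:
        raise ValueError(f"need more rows than parameters (n={n} <= 3)")
    X = np.column_stack([
        np.ones(n),
        rows["promoter_norm"].to_numpy(float),
        rows["body_norm"].to_numpy(float),
    ])
    if np.linalg.matrix_rank(X) < 3:
        # name which regressors are collinear
        culprit = "promoter/body" if np.linalg.matrix_rank(X[:, 1:]) < 2 else \
            "intercept/promoter/body"
        raise ValueError(f"rank-deficient design: collinear columns ({culprit})")
    res = sm.OLS(rows["treated_norm"].to_numpy(float), X).fit()
    se = dict(zip(_TERMS, (float(v) for v in res.bse)))
    t = dict(zip(_TERMS, (float(v) for v in res.tvalues)))
    p = dict(zip(_TERMS, (float(v) for v in res.pvalues)))
    return ModelFit(
        beta_intercept=float(res.params[0]),
        beta_promoter=float(res.params[1]),
        beta_body=float(res.params[2]),
        se=se, t=t, p=p, n=n, r_squared=float(res.rsquared),
    )


def fit_from_tables(de_records: pd.DataFrame, meth_records: pd.DataFrame,
                    logfc_min: float = 1.2) -> ModelFit:
    """Full path: row selection, normalization, OLS."""
    rows = select_model_rows(de_records, meth_records, logfc_min)
    return fit_linear_model(prepare_model_input(rows))
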