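#!/usr/bin/env python
"""Fit the methylation-expression linear model per cell line.

Selects genes with |logFC| > 1.2 and any positive methylation, min-max
normalizes treated expression and both methylation levels, and fits
treated ~ promoter + body by OLS.  The expected signature of promoter
silencing is a significant negative promoter coefficient and a null
gene-body coefficient.  Writes one fit report JSON per line under
<out>/model/.
"""

import argparse
from pathlib import Path

from dipnet import io, regression


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # unused; uniform interface
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--logfc-min", type=float, default=1.2)
    args = ap.parse_args()
    outdir = args.out / "model"
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("cell_a", "cell_b"):
        simdir = args.out / "sim" / name
        de = io.read_tsv(simdir / "de_table.tsv", required=io.DE_COLUMNS)
        meth = io.read_tsv(simdir / "methylation.tsv", required=io.METH_COLUMNS)
        fit = regression.fit_from_tables(de, meth, logfc_min=args.logfc_min)
        io.write_json(fit.to_dict(), outdir / f"{name}_fit.json")
        verdict = "significant" if fit.p["promoter"] < 0.05 else "not significant"
        print(f"{name}: n={fit.n}, beta_promoter={fit.beta_promoter:.3f} "
              f"(p={fit.p['promoter']:.2e}, {verdict}), "
              f"beta_body={fit.beta_body:.3f} (p={fit.p['body']:.2f}), "
              f"R^2={fit.r_squared:.3f}")


if __name__ == "__main__":
    main()
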