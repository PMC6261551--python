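#!/usr/bin/env python
"""Build and compare unconstrained vs DiP-constrained interaction maps.

The unconstrained map is induced on all DEGs of a line; the constrained map
on the DEGs surviving the antigen-style DiP thresholds.  lincRNA
associations from the 1 Mb window are overlaid on the unconstrained map.
Reports connectivity summaries (components, singletons, largest component)
and the retention fractions showing how the constraints dissolve
connectivity.  Writes node/edge tables and summary JSONs under <out>/maps/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dipnet import antigens, dip, io, networks


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # unused; uniform interface
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--min-score", type=float, default=0.0)
    args = ap.parse_args()
    outdir = args.out / "maps"
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("cell_a", "cell_b"):
        simdir = args.out / "sim" / name
        de = io.read_tsv(simdir / "de_table.tsv", required=io.DE_COLUMNS)
        meth = io.read_tsv(simdir / "methylation.tsv", required=io.METH_COLUMNS)
        edges = io.read_tsv(simdir / "interactions.tsv", required=io.EDGE_COLUMNS)
        degs = dip.select_degs(de, logfc_min=1.0, fdr_max=0.05)
        gene_list = sorted(degs["gene_id"])
        full = networks.induce_map(gene_list, edges, args.min_score)

        assign_path = args.out / "targets" / "lincrna_targets.tsv"
        if name == "cell_a" and assign_path.exists():
            assignments = io.read_tsv(assign_path)
            full = networks.overlay_ncrna(full, assignments, window_mb=1)

        dipdf = de.merge(meth, on="gene_id", how="left")
        kept = antigens.constrain_antigen_genes(set(gene_list), dipdf)
        constrained = networks.induce_map(kept, edges, args.min_score,
                                          label="constrained")
        report = networks.compare_maps(full, constrained)
        io.write_json(report, outdir / f"{name}_comparison.json")
        edge_rows = [(a, b, d.get("score", ""), d.get("kind", "interaction"))
                     for a, b, d in full.graph.edges(data=True)]
        io.write_tsv(pd.DataFrame(edge_rows,
                                  columns=["node_a", "node_b", "score", "kind"]),
                     outdir / f"{name}_edges.tsv")
        s_un = report["summary_unconstrained"]
        s_con = report["summary_constrained"]
        print(f"{name}: unconstrained {s_un['n_nodes']} nodes / "
              f"{s_un['n_edges']} edges ({s_un['n_singletons']} singletons, "
              f"largest component {s_un['largest_component']}); "
              f"constrained {s_con['n_nodes']} nodes / {s_con['n_edges']} edges "
              f"({s_con['n_singletons']} singletons); "
              f"edge retention {report['edge_retention']:.2f}, "
              f"{len(full.ncrna_overlays)} ncRNA overlays")


if __name__ == "__main__":
    main()
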