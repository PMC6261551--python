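#!/usr/bin/env python
"""Assign lincRNA targets by genomic proximity and pseudogene parents by
sequence identity.

lincRNA targets: genes intersecting the +/-1/2/3 Mb windows around each
lincRNA locus, with nearest-priority flags and cis/trans classification.
Pseudogene parents: best global-alignment hit among candidate parents plus
read-evidence classification (unique reads, or shared reads with identity
< 90%).  Writes assignment tables under <out>/targets/ for cell_a.
"""

import argparse
from pathlib import Path

from dipnet import io, targets


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # unused; uniform interface
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    simdir = args.out / "sim" / "cell_a"
    outdir = args.out / "targets"
    outdir.mkdir(parents=True, exist_ok=True)

    bed = io.read_bed(simdir / "annotation.bed")
    feats = targets.intervals_from_bed(bed)
    lincs = [f for f in feats if f.feature_class == "lincRNA"]
    genes = [f for f in feats if f.feature_class == "gene"]
    assigns = targets.prioritize_nearest(
        targets.find_all_window_targets(lincs, genes, (1, 2, 3)))
    gene_by_id = {g.feature_id: g for g in genes}
    for t in assigns:
        linc = next(f for f in lincs if f.feature_id == t.ncrna_id)
        t.regulation_class = targets.classify_regulation(
            linc, gene_by_id[t.target_gene_id], t.window_mb)
    table = targets.assignments_to_frame(assigns)
    io.write_tsv(table, outdir / "lincrna_targets.tsv")
    n1 = (table["window_mb"] == 1).sum()
    truth = io.read_json(simdir / "truth.json")
    truth_pairs = {(l, g) for l, gs in truth["lincrna_target_map"].items()
                   for g in gs}
    found_pairs = {(r.ncrna_id, r.target_gene_id)
                   for r in table[table["window_mb"] == 1].itertuples()}
    print(f"lincRNA targets: {n1} pairs at 1 Mb "
          f"({len(found_pairs & truth_pairs)}/{len(truth_pairs)} planted recovered), "
          f"{len(table)} across all windows")

    seqs = io.read_fasta(simdir / "pseudogene_families.fasta")
    parents = {k: v for k, v in seqs.items() if k.startswith("PAR")}
    pseudos = {k: v for k, v in seqs.items() if k.startswith("PSG")}
    reads = io.read_tsv(simdir / "read_evidence.tsv",
                        required=io.READ_EVIDENCE_COLUMNS)
    pas = targets.assign_parental(pseudos, parents, reads)
    import pandas as pd
    ptable = pd.DataFrame([pa.__dict__ for pa in pas])
    io.write_tsv(ptable, outdir / "pseudogene_parents.tsv")
    correct = sum(1 for pa in pas
                  if truth["pseudogene_parent_map"][pa.pseudogene_id][0]
                  == pa.parental_id)
    print(f"pseudogene parents: {correct}/{len(pas)} planted parents recovered; "
          f"evidence classes: {ptable['evidence'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
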