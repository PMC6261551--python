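#!/usr/bin/env python
"""Match tumor-antigen peptides against the proteome, then constrain by DiP.

Runs best-match (exact) and one-mismatch peptide matching of the curated
peptide table against the protein FASTA, and restricts the matched gene list
with the DiP thresholds (logFC > 1.5 or < -1.5; promoter > 2.9 or gene body
> 8.39 where methylation was measured).  Writes hit tables and the
constrained gene lists under <out>/antigens/.
"""

import argparse
from pathlib import Path

from dipnet import antigens, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # unused; uniform interface
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    outdir = args.out / "antigens"
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("cell_a", "cell_b"):
        simdir = args.out / "sim" / name
        proteins = io.read_fasta(simdir / "proteins.fasta")
        pep_table = io.read_tsv(simdir / "peptides.tsv",
                                required=io.PEPTIDE_COLUMNS)
        peptides = antigens.peptides_from_table(pep_table)
        exact = antigens.match_exact(peptides, proteins)
        om = antigens.match_one_mismatch(peptides, proteins)
        io.write_tsv(exact, outdir / f"{name}_hits_exact.tsv")
        io.write_tsv(om, outdir / f"{name}_hits_one_mismatch.tsv")

        gene_of_protein = dict(zip(pep_table["protein_id"], pep_table["gene_name"]))
        hit_genes = {gene_of_protein[p] for p in om["protein_id"]}
        de = io.read_tsv(simdir / "de_table.tsv", required=io.DE_COLUMNS)
        meth = io.read_tsv(simdir / "methylation.tsv", required=io.METH_COLUMNS)
        dipdf = de.merge(meth, on="gene_id", how="left")
        kept = antigens.constrain_antigen_genes(hit_genes, dipdf)
        (outdir / f"{name}_constrained_genes.txt").write_text(
            "\n".join(kept) + ("\n" if kept else ""))
        print(f"{name}: {len(exact)} exact hits, {len(om)} one-mismatch hits "
              f"({len(om) - len(exact)} with a substitution); "
              f"{len(hit_genes)} antigen genes -> {len(kept)} after DiP constraint")


if __name__ == "__main__":
    main()
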