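# Methods

## The differential-profile (DiP) model

Each cell line contributes two per-gene tables: differential expression
(logFC = log₂ fold change treated vs tumor, logCPM, FDR, FPKM abundances) and
methylation (promoter level, gene-body level). DEGs are genes with
|logFC| > 1 and FDR < 0.05. The joint re-activation filter selects genes with
logFC above the transcriptome threshold *T* and promoter methylation above
the methylome threshold *M*. Both thresholds are quantiles (default the
median) with linear interpolation between order statistics; by default they
are computed over the upregulated DEGs' logFC values and those genes'
promoter levels — which population the quantiles are taken over is
genuinely open, so it is an argument of `dip.compute_dip_thresholds`.
Two deliberate readings are encoded as defaults and documented here:

- The methylome threshold gates on the **promoter level only**. A gene whose
  gene body is heavily methylated but whose promoter is not (the CDH1-like
  pattern: promoter 3.44 ≤ 4.25 with gene body 21.02) does not pass M. The
  gene-body level is always carried and reported.
- Ties at a threshold are excluded (strict `>`), matching the "T > 2.24"
  notation of threshold tables.
- Genes missing from the methylation table are flagged
  (`has_methylation = False`), logged, and can never be re-activated.

Raising either threshold can only shrink the re-activated set (monotonicity;
property-tested).

## Methylation–expression regression

Rows: genes with |logFC| > 1.2 and positive methylation at promoter or gene
body. Variables: treated FPKM and both methylation levels, each min-max
normalized to [0, 1] **over the selected rows** (normalizing after filtering,
since only the analyzed values are scaled). Model: OLS of
`treated ~ promoter + body` with intercept and two-sided t-tests. A GLS fit
with no stated correlation structure is identical to OLS, so only OLS is
implemented. Constant columns are rejected (min-max undefined); rank-deficient
designs raise an error naming the collinear columns; n must exceed the three
parameters.

## Synthetic world

The generator's defaults are the stated world of the package; none were
tuned against test outcomes.

- **Expression/methylation coupling.** Promoter and gene-body methylation
  are U(0, 1) on the normalized scale, emitted at scales 8.5 and 16.8 so the
  population medians sit near the magnitudes a real profile prints.
  Treated expression is `0.8 + β_p·promoter + β_b·body + N(0, σ)` with
  defaults β_p = −0.5, β_b = 0, σ = 0.1, mapped to an FPKM-like scale by a
  positive affine transform (×100, floor 1 FPKM). Min-max renormalization is
  invariant to positive affine maps, so the planted coefficients survive the
  round trip exactly at σ = 0; with β_p = −1 and β_b = 0 the normalized
  slope is exactly −1 (the treated range equals the promoter range).
- **Re-activated subset.** 10% of genes, drawn from the upper promoter-
  methylation half, receive logFC ~ U(3, 6); the remaining upper-half genes
  receive U(−2, 0) and the lower half U(−1, 2). The disjoint ranges make the
  planted set *exactly* the set passing "promoter > median and logFC >
  median of positive logFC", recomputable from the emitted files alone. This
  construction requires `frac_reactivated` well below 0.5 (enforced at n/2);
  tumor abundances are back-computed from logFC with pseudocount 0.01, so
  the emitted logFC column is exactly consistent with the abundances.
  FDR is planted metadata (small for signal genes, uniform otherwise) —
  differential-expression calling from counts is out of scope.
- **Annotation.** One pseudo-chromosome, 0-based half-open BED. Each lincRNA
  owns an 8 Mb territory: two target genes at gaps U(10 kb, 900 kb) and one
  decoy at 3.1–3.9 Mb; all other genes sit in a distant band. Hence a ±1 Mb
  scan recovers exactly the planted target map and decoys fail even ±3 Mb.
  Infeasible placements (chromosome too short) raise an error naming the
  constraint.
- **Pseudogenes.** Substitution-only mutants of 300 nt parents at identities
  0.85 and 0.95 per family (straddling the 0.90 evidence cut); read evidence
  plants all three classes (shared reads at low identity, pseudogene-only
  reads, shared-only at high identity).
- **Antigens.** Proteins of 150–1200 aa over the 20-letter alphabet; planted
  peptides (9–12-mers) copied from a window exactly (even indices) or with
  exactly one substitution (odd indices); a subset of exact peptides is
  emitted in the decorated `XX(Y)ZZ[XXYZZ]` notation. Protein *i* is the
  product of gene *i*, so antigen hits join onto the DiP table.
- **Network.** Erdős–Rényi background at p = 0.01 plus two 4-cliques planted
  among re-activated genes; undirected, deduplicated, no self-loops.

What the generator does **not** emulate: read-level data (no FASTQ, no
bisulfite model), biological replicate structure and dispersion (FDR is
planted, not computed), multiple chromosomes, indels in pseudogenes or
peptide variants, and realistic degree distributions (the background is
homogeneous ER). A green test therefore establishes the correctness of the
pipeline's logic on profiles with the stated statistical structure, not
robustness to alignment artifacts or count noise.

## Target and parental assignment

Coordinates are 0-based half-open throughout; any 1-based value (peptide
`loc`) is explicit. A gene is a window target when its interval intersects
`[start − w, end + w)`; the gap is boundary-to-boundary (0 on overlap),
robust to feature length, strand-agnostic. Nearest-priority flags exactly
one target per (lincRNA, window), ties broken lexicographically by gene id.
cis = same chromosome within the window; trans otherwise. The default window
is 1 Mb; 2 and 3 Mb are available (the choice is arbitrary by the nature of
the problem, and window nesting is property-tested).

Sequence identity replaces a BLAST e-value ranking with a global pairwise
alignment (unit match score, mismatch 0, affine gaps −2/−0.5); identity =
matches / alignment length. Under a fixed scoring scheme the best-score
argmax gives the same parent ordering an e-value ranking would, at desk
scale and dependency-free. Parental evidence: `unique_reads` if any read
maps to the pseudogene only; else `shared_reads_low_identity` if shared
reads exist and identity < 0.90; else `none`.

## Antigen matching

Peptide normalization: a bracketed canonical form `[...]` wins; otherwise
parentheses around single residues are stripped; uppercase; non-amino-acid
residues are rejected by name. "One-mismatch" is Hamming distance ≤ 1 —
substitutions only, equal length, no indels (standard epitope near-match
semantics with a well-defined exhaustive oracle); exact hits are therefore
always a subset of one-mismatch hits. `loc` is the 1-based start of the
matched window. Blank methylation cells mean *not measured*, not zero: such
genes are constrained on expression alone.

## Network maps

Maps are induced subgraphs over a scored edge list: all listed genes are
nodes (singletons kept), edges need both endpoints in the list and score ≥
`min_score` (default 0 — no confidence cutoff is imposed). ncRNA overlays
are typed links to in-map targets only and are excluded from connectivity
summaries, which count gene nodes and interaction edges (components,
singletons, degree histogram, largest component). Map comparison requires
the constrained map to be a subset (a filter must only remove) and reports
node/edge retention and singleton/component deltas.

## Numerical choices

- Quantiles: NumPy linear interpolation; agreement with a sort-based oracle
  to 1e-12 is property-tested.
- Enrichment: hypergeometric upper tail `P(X ≥ k)` via `hypergeom.sf(k−1)`,
  Benjamini–Hochberg across sets; q ≥ p always.
- logFC: base 2 with pseudocount 0.01 on FPKM abundances.
- Determinism: every generator consumes `numpy.random.default_rng` seeded
  from the config; sub-generators use fixed seed offsets (+1 … +4), so the
  same seed yields byte-identical files.

## Known limitations

- The DiP threshold population default (upregulated DEGs) is one of several
  defensible readings; results shift with the choice, which is why it is a
  parameter.
- The pairwise-identity scorer is not BLAST: e-values, composition-based
  statistics and local alignment are not modeled; only the best-hit ranking
  is preserved by construction.
- Enrichment assumes a fully annotated universe; genes outside it are an
  error, not silently dropped.
- The network module does no layout, module detection beyond connected
  components, or live database queries.
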