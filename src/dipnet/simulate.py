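"""Synthetic multi-omics generator with planted ground truth.

Emulates the inputs of a coupled RNA-Seq / RRBS differential-profile study of
two melanoma cell lines under demethylating (5-Aza-2'-deoxycytidine)
treatment: per-gene differential-expression and methylation tables, gene and
lincRNA coordinates, pseudogene families, a tumor-antigen peptide database,
and a protein-interaction edge list.  Every planted structure (re-activated
genes, lincRNA cis-targets, pseudogene parents, peptide locations, cliques)
is recorded in a :class:`PlantedTruth` and is recoverable from the emitted
files alone by brute-force scanning.

The statistical structure planted in the expression/methylation pair is the
one the downstream regression is meant to detect: on normalized scales,

    treated = intercept + beta_promoter * promoter + beta_body * body + noise

with ``beta_promoter`` negative (promoter hypermethylation silences) and
``beta_body`` zero (gene-body methylation carries no signal).  A
``frac_reactivated`` subset of genes is hypermethylated at the promoter
(above the population median) *and* strongly up-regulated after treatment
(logFC above the median of positive logFC values) -- the "re-activated" genes
the joint quantile filter is designed to isolate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

# log2 fold change uses a small pseudocount on FPKM abundances (edgeR flavor)
LOGFC_PSEUDOCOUNT = 0.01

# raw-scale spans for the emitted values; medians land near the magnitudes a
# real profile prints (promoter median ~4.25, body values up to ~20 FPKM-free)
_PROMOTER_SCALE = 8.5
_BODY_SCALE = 16.8
_FPKM_SCALE = 100.0
_FPKM_FLOOR = 1.0
_EXPR_INTERCEPT = 0.8

_DNA = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_BIOTYPES = np.array(
    ["protein_coding", "antisense", "pseudogene", "processed_transcript",
     "sense_overlapping", "NA"]
)
_BIOTYPE_P = np.array([0.90, 0.03, 0.03, 0.02, 0.01, 0.01])


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the generator; all downstream defaults derive from it."""

    n_genes: int = 1000
    n_lincrna: int = 8
    n_pseudogene_families: int = 6
    n_proteins: int = 20
    n_peptides: int = 30
    frac_reactivated: float = 0.1
    beta_promoter: float = -0.5
    beta_body: float = 0.0
    noise_sd: float = 0.1
    chrom_length: int = 250_000_000
    seed: int = 0
    background_edge_p: float = 0.01

    def __post_init__(self):
        for name in ("n_genes", "n_lincrna", "n_pseudogene_families",
                     "n_proteins", "n_peptides", "chrom_length"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("frac_reactivated", "beta_promoter", "beta_body",
                     "noise_sd", "background_edge_p"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.frac_reactivated <= 1.0:
            raise ValueError("frac_reactivated must lie in [0, 1]")
        if not 0.0 <= self.background_edge_p <= 1.0:
            raise ValueError("background_edge_p must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth written alongside the synthetic files (truth JSON)."""

    reactivated_gene_ids: set[str] = field(default_factory=set)
    lincrna_target_map: dict[str, list[str]] = field(default_factory=dict)
    pseudogene_parent_map: dict[str, tuple[str, float]] = field(default_factory=dict)
    peptide_plant_map: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    planted_cliques: list[list[str]] = field(default_factory=list)

    def merge(self, other: "PlantedTruth") -> "PlantedTruth":
        self.reactivated_gene_ids |= other.reactivated_gene_ids
        self.lincrna_target_map.update(other.lincrna_target_map)
        self.pseudogene_parent_map.update(other.pseudogene_parent_map)
        self.peptide_plant_map.update(other.peptide_plant_map)
        self.planted_cliques.extend(other.planted_cliques)
        return self

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["reactivated_gene_ids"] = sorted(self.reactivated_gene_ids)
        return d


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def _lincrna_ids(n: int) -> list[str]:
    return [f"LINC{i:04d}" for i in range(n)]


def generate_expression_methylation(config: SimulationConfig):
    """Emit the DE table, the methylation table, and the planted truth.

    Construction guarantees (for ``frac_reactivated`` well below 0.5):

    * the planted re-activated genes -- and only they -- have promoter
      methylation strictly above the gene-population median *and* logFC
      strictly above the median of positive logFC values;
    * the emitted ``logFC`` column equals
      ``log2((treated + pc) / (tumor + pc))`` on the emitted abundances;
    * with ``noise_sd = 0`` the planted coefficients are exactly recoverable
      by least squares on min-max-normalized emitted columns.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    ids = _gene_ids(n)
    n_react = int(round(config.frac_reactivated * n))
    if n_react > n // 2:
        raise ValueError(
            "frac_reactivated too large: the planted set must fit in the "
            "upper promoter-methylation half"
        )

    u_prom = rng.uniform(0.0, 1.0, n)
    u_body = rng.uniform(0.0, 1.0, n)

    order = np.argsort(u_prom)
    upper_half = order[-(n // 2):] if n else order
    planted_idx = rng.choice(upper_half, size=n_react, replace=False)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_idx] = True
    upper_mask = np.zeros(n, dtype=bool)
    upper_mask[upper_half] = True

    # planted: strong up-regulation; other hypermethylated genes: stay down;
    # lower-half genes: background fold changes. The disjoint ranges make the
    # planted set exactly recoverable from the files by the quantile rule.
    logfc = np.empty(n)
    logfc[planted_mask] = rng.uniform(3.0, 6.0, planted_mask.sum())
    other_upper = upper_mask & ~planted_mask
    logfc[other_upper] = rng.uniform(-2.0, 0.0, other_upper.sum())
    logfc[~upper_mask] = rng.uniform(-1.0, 2.0, (~upper_mask).sum())

    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    treated_norm = (_EXPR_INTERCEPT
                    + config.beta_promoter * u_prom
                    + config.beta_body * u_body
                    + noise)
    # positive affine map to an FPKM-like scale; min-max renormalization
    # downstream is invariant to it, so planted betas survive exactly
    treated_fpkm = (treated_norm - treated_norm.min()) * _FPKM_SCALE + _FPKM_FLOOR
    pc = LOGFC_PSEUDOCOUNT
    tumor_fpkm = (treated_fpkm + pc) / np.exp2(logfc) - pc
    if (tumor_fpkm < 0).any():
        raise AssertionError("internal: abundance construction produced negative FPKM")
    logfc_emitted = np.log2((treated_fpkm + pc) / (tumor_fpkm + pc))

    fdr = rng.uniform(0.0, 1.0, n)
    fdr[planted_mask] = rng.uniform(1e-6, 0.01, planted_mask.sum())
    logcpm = np.log2((treated_fpkm + tumor_fpkm) / 2.0 + 1.0)
    biotype = rng.choice(_BIOTYPES, size=n, p=_BIOTYPE_P)

    de = pd.DataFrame({
        "gene_id": ids,
        "biotype": biotype,
        "logFC": logfc_emitted,
        "logCPM": logcpm,
        "fdr": fdr,
        "tumor_fpkm": tumor_fpkm,
        "treated_fpkm": treated_fpkm,
    })

    # lincRNA rows carry expression only (no promoter/body methylation calls)
    if config.n_lincrna:
        lids = _lincrna_ids(config.n_lincrna)
        l_logfc = rng.normal(0.0, 2.0, config.n_lincrna)
        l_treated = rng.uniform(1.0, 50.0, config.n_lincrna)
        l_tumor = np.maximum((l_treated + pc) / np.exp2(l_logfc) - pc, 0.0)
        linc = pd.DataFrame({
            "gene_id": lids,
            "biotype": "lincRNA",
            "logFC": np.log2((l_treated + pc) / (l_tumor + pc)),
            "logCPM": np.log2((l_treated + l_tumor) / 2.0 + 1.0),
            "fdr": rng.uniform(0.0, 1.0, config.n_lincrna),
            "tumor_fpkm": l_tumor,
            "treated_fpkm": l_treated,
        })
        de = pd.concat([de, linc], ignore_index=True)

    meth = pd.DataFrame({
        "gene_id": ids,
        "promoter_level": u_prom * _PROMOTER_SCALE,
        "gene_body_level": u_body * _BODY_SCALE,
    })

    truth = PlantedTruth(reactivated_gene_ids={ids[i] for i in planted_idx})
    return de, meth, truth


# --- genomic annotation -----------------------------------------------------

_REGION_SPAN = 8_000_000      # per-lincRNA territory; keeps windows disjoint
_REGION_OFFSET = 1_000_000    # left margin so -1 Mb windows stay on-chromosome
_LINC_LEN = 10_000
_TARGET_LEN = 20_000
_TARGETS_PER_LINC = 2


def generate_annotation(config: SimulationConfig):
    """Place genes and lincRNAs on one pseudo-chromosome (BED, 0-based).

    Each lincRNA owns an 8 Mb territory holding two planted target genes
    within 0.9 Mb and one decoy gene 3.1-3.9 Mb away; all remaining genes go
    to a distant band.  Consequently a +/-1 Mb scan recovers exactly the
    planted target map, and the decoys fall outside even the +/-3 Mb window.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = _gene_ids(config.n_genes)
    linc_ids = _lincrna_ids(config.n_lincrna)
    n_special = config.n_lincrna * (_TARGETS_PER_LINC + 1)
    if n_special > config.n_genes:
        raise ValueError(
            "n_genes too small: each lincRNA needs "
            f"{_TARGETS_PER_LINC} targets and 1 decoy ({n_special} genes)"
        )

    rows = []
    truth = PlantedTruth()
    next_gene = 0
    for j, lid in enumerate(linc_ids):
        base = _REGION_OFFSET + j * _REGION_SPAN
        rows.append(("chrS", base, base + _LINC_LEN, lid, 0,
                     "+" if rng.random() < 0.5 else "-"))
        targets = []
        for _ in range(_TARGETS_PER_LINC):
            gid = gene_ids[next_gene]; next_gene += 1
            gap = int(rng.integers(10_000, 900_000))
            if rng.random() < 0.5:
                start = base + _LINC_LEN + gap
            else:
                start = base - gap - _TARGET_LEN
            rows.append(("chrS", start, start + _TARGET_LEN, gid, 0,
                         "+" if rng.random() < 0.5 else "-"))
            targets.append(gid)
        gid = gene_ids[next_gene]; next_gene += 1
        gap = int(rng.integers(3_100_000, 3_900_000))
        start = base + _LINC_LEN + gap
        rows.append(("chrS", start, start + _TARGET_LEN, gid, 0, "+"))
        truth.lincrna_target_map[lid] = sorted(targets)

    band_start = _REGION_OFFSET + config.n_lincrna * _REGION_SPAN + 4_000_000
    spacing = 5_000
    n_rest = config.n_genes - next_gene
    end_needed = band_start + n_rest * spacing + _TARGET_LEN
    if end_needed > config.chrom_length:
        raise ValueError(
            f"chrom_length={config.chrom_length} too small: placement needs "
            f"{end_needed} bp (lincRNA territories + gene band)"
        )
    for k, gid in enumerate(gene_ids[next_gene:]):
        start = band_start + k * spacing
        rows.append(("chrS", start, start + 2_000, gid, 0,
                     "+" if rng.random() < 0.5 else "-"))

    bed = pd.DataFrame(rows, columns=io.BED_COLUMNS)
    return bed, truth


# --- pseudogene families ----------------------------------------------------

_PARENT_LEN = 300
_FAMILY_IDENTITIES = (0.85, 0.95)  # straddle the 0.90 parental-evidence cut


def _mutate(seq: str, n_sub: int, rng) -> str:
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    for p in pos:
        choices = _DNA[_DNA != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return "".join(arr)


def make_pseudogene(parent_seq: str, identity: float, rng) -> tuple[str, float]:
    """Substitution-only copy of ``parent_seq`` at the requested identity.

    Returns the mutated sequence and the realized identity (1 - n_sub/len).
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"requested identity must lie in (0, 1], got {identity}")
    n_sub = int(round((1.0 - identity) * len(parent_seq)))
    return _mutate(parent_seq, n_sub, rng), 1.0 - n_sub / len(parent_seq)


def generate_pseudogene_families(config: SimulationConfig):
    """Parents + pseudogenes FASTA, a read-evidence table, and truth.

    Each family has one parent and two pseudogenes whose identities straddle
    0.90.  The read table plants the two parental-evidence classes: the
    low-identity pseudogene gets reads shared with the parent; the
    high-identity one alternates between pseudogene-only reads (unique
    evidence) and shared-only reads (no admissible evidence).
    """
    rng = np.random.default_rng(config.seed + 2)
    seqs: dict[str, str] = {}
    reads = []
    truth = PlantedTruth()
    read_i = 0
    for f in range(config.n_pseudogene_families):
        parent_id = f"PAR{f:02d}"
        parent = "".join(rng.choice(_DNA, size=_PARENT_LEN))
        seqs[parent_id] = parent
        for k, ident in enumerate(_FAMILY_IDENTITIES):
            pid = f"PSG{f:02d}_{k}"
            seqs[pid], realized = make_pseudogene(parent, ident, rng)
            truth.pseudogene_parent_map[pid] = (parent_id, realized)
            if ident < 0.90:
                pattern = [(1, 1)] * 5                  # shared reads
            elif f % 2 == 0:
                pattern = [(1, 0)] * 3 + [(1, 1)] * 2   # some pseudogene-only
            else:
                pattern = [(1, 1)] * 5                  # shared, high identity
            for mp, mpar in pattern:
                reads.append((f"read{read_i:05d}", pid, mp, mpar))
                read_i += 1
    read_table = pd.DataFrame(reads, columns=io.READ_EVIDENCE_COLUMNS)
    return seqs, read_table, truth


# --- antigen database -------------------------------------------------------

def generate_antigen_db(config: SimulationConfig):
    """Protein FASTA + peptide table with planted exact / one-mismatch hits.

    Even-indexed peptides are exact copies of a protein window; odd-indexed
    ones differ from the window at exactly one residue.  Every third exact
    peptide is emitted in the decorated ``XX(Y)ZZ[XXYZZ]`` raw notation to
    exercise normalization.
    """
    rng = np.random.default_rng(config.seed + 3)
    if config.n_proteins == 0 and config.n_peptides > 0:
        raise ValueError("cannot plant peptides without proteins")
    proteins = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(150, 1200))
        proteins[f"PROT{i:03d}"] = "".join(rng.choice(_AA, size=length))
    prot_ids = list(proteins)
    # protein i is the product of gene i, so antigen hits join onto the DiP
    gene_of = {pid: (_gene_ids(config.n_genes)[i] if i < config.n_genes
                     else f"GN{i:03d}") for i, pid in enumerate(prot_ids)}

    rows = []
    truth = PlantedTruth()
    for k in range(config.n_peptides):
        pep_id = f"T{k:06d}"
        prot_id = prot_ids[int(rng.integers(len(prot_ids)))]
        prot = proteins[prot_id]
        plen = int(rng.integers(9, 13))
        loc = int(rng.integers(1, len(prot) - plen + 2))  # 1-based start
        window = prot[loc - 1: loc - 1 + plen]
        n_mm = k % 2
        if n_mm:
            p = int(rng.integers(plen))
            choices = _AA[_AA != window[p]]
            pep = window[:p] + str(choices[rng.integers(len(choices))]) + window[p + 1:]
        else:
            pep = window
        raw = pep
        if n_mm == 0 and k % 6 == 0 and plen >= 4:
            q = int(rng.integers(1, plen - 1))
            raw = f"{pep[:q]}({pep[q]}){pep[q + 1:]}[{pep}]"
        rows.append((gene_of[prot_id], prot_id, len(prot), pep_id, raw, loc))
        truth.peptide_plant_map[pep_id] = (prot_id, loc, n_mm)

    peptides = pd.DataFrame(rows, columns=io.PEPTIDE_COLUMNS)
    return proteins, peptides, truth


# --- interaction network ----------------------------------------------------

def generate_interaction_network(config: SimulationConfig,
                                 gene_ids: list[str] | None = None,
                                 clique_members: list[list[str]] | None = None):
    """Undirected deduplicated edge list: planted cliques over an ER background.

    By default two 4-cliques are planted among the first gene ids; callers
    (e.g. :func:`generate_all`) can plant cliques among the re-activated set.
    """
    rng = np.random.default_rng(config.seed + 4)
    if gene_ids is None:
        gene_ids = _gene_ids(config.n_genes)
    n = len(gene_ids)
    if clique_members is None:
        clique_members = []
        if n >= 8:
            clique_members = [gene_ids[:4], gene_ids[4:8]]

    edges: dict[tuple[str, str], float] = {}
    # background Erdos-Renyi over unordered pairs
    p = config.background_edge_p
    if n >= 2 and p > 0:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < p
        scores = np.round(rng.uniform(0.15, 0.99, int(mask.sum())), 3)
        for a, b, s in zip(iu[mask], ju[mask], scores):
            edges[(gene_ids[a], gene_ids[b])] = float(s)
    for members in clique_members:
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                key = tuple(sorted((members[x], members[y])))
                edges[key] = float(np.round(rng.uniform(0.7, 0.99), 3))

    edge_df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=io.EDGE_COLUMNS,
    )
    truth = PlantedTruth(planted_cliques=[sorted(m) for m in clique_members])
    return edge_df, truth


# --- orchestration ----------------------------------------------------------

@dataclass
class SimulatedData:
    config: SimulationConfig
    de: pd.DataFrame
    meth: pd.DataFrame
    annotation: pd.DataFrame
    pseudogene_seqs: dict[str, str]
    read_evidence: pd.DataFrame
    proteins: dict[str, str]
    peptides: pd.DataFrame
    edges: pd.DataFrame
    truth: PlantedTruth

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_tsv(self.de, out / "de_table.tsv")
        io.write_tsv(self.meth, out / "methylation.tsv")
        io.write_bed(self.annotation, out / "annotation.bed")
        io.write_fasta(self.pseudogene_seqs, out / "pseudogene_families.fasta")
        io.write_tsv(self.read_evidence, out / "read_evidence.tsv")
        io.write_fasta(self.proteins, out / "proteins.fasta")
        io.write_tsv(self.peptides, out / "peptides.tsv")
        io.write_tsv(self.edges, out / "interactions.tsv")
        io.write_json(self.truth.to_json_dict(), out / "truth.json")


def generate_all(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedData:
    """Run every generator with a shared config; optionally write all files."""
    de, meth, truth = generate_expression_methylation(config)
    bed, t2 = generate_annotation(config)
    pseqs, reads, t3 = generate_pseudogene_families(config)
    prots, peps, t4 = generate_antigen_db(config)
    reactivated = sorted(truth.reactivated_gene_ids)
    cliques = [reactivated[:4], reactivated[4:8]] if len(reactivated) >= 8 else None
    edges, t5 = generate_interaction_network(
        config, gene_ids=_gene_ids(config.n_genes), clique_members=cliques)
    for t in (t2, t3, t4, t5):
        truth.merge(t)
    data = SimulatedData(config, de, meth, bed, pseqs, reads, prots, peps, edges, truth)
    if outdir is not None:
        data.write(outdir)
    return data
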