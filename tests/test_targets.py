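"""lincRNA window targets, nearest prioritization, cis/trans, sequence
identity and pseudogene parental assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dipnet import simulate, targets
from dipnet.targets import GenomicInterval


def gotoh_score(a, b, match=1.0, mismatch=0.0, gap_open=-2.0, gap_extend=-0.5):
    """Independent affine-gap global alignment score (Gotoh DP)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + int(rng.integers(1_000, 100_000)),
                                   feature_id=f"F{i:04d}"))
    return out


class TestIntervals:
    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    @given(st.integers(0, 1000), st.integers(1, 100),
           st.integers(0, 1000), st.integers(1, 100))
    def test_gap_symmetric_zero_iff_intersect(self, s1, l1, s2, l2):
        a = GenomicInterval("c", s1, s1 + l1)
        b = GenomicInterval("c", s2, s2 + l2)
        g = targets.gap_bp(a, b)
        assert g == targets.gap_bp(b, a)
        intersect = a.start < b.end and b.start < a.end
        assert (g == 0) == intersect


class TestWindowTargets:
    def test_inside_window_included_with_gap(self):
        nc = GenomicInterval("chr1", 5_000_000, 5_010_000, feature_id="L1",
                             feature_class="lincRNA")
        gene = GenomicInterval("chr1", 5_400_000, 5_420_000, feature_id="G1")
        hits = targets.find_window_targets(nc, [gene], 1)
        assert len(hits) == 1 and hits[0].gap_bp == 390_000

    def test_other_chromosome_excluded(self):
        nc = GenomicInterval("chr1", 0, 10_000, feature_id="L1")
        gene = GenomicInterval("chr2", 0, 10_000, feature_id="G1")
        assert targets.find_window_targets(nc, [gene], 3) == []

    def test_decoy_beyond_three_mb_excluded(self):
        nc = GenomicInterval("chr1", 5_000_000, 5_010_000, feature_id="L1")
        decoy = GenomicInterval("chr1", 5_010_000 + 3_500_001,
                                5_010_000 + 3_520_001, feature_id="D1")
        for w in (1, 2, 3):
            assert targets.find_window_targets(nc, [decoy], w) == []

    def test_matches_bruteforce_scan_and_nesting(self, rng):
        """Against an O(n^2) all-pairs oracle at all three window sizes."""
        feats = random_intervals(rng, 200)
        ncrnas, genes = feats[:40], feats[40:]
        for nc in ncrnas:
            sets = {}
            for w in (1, 2, 3):
                hits = {t.target_gene_id
                        for t in targets.find_window_targets(nc, genes, w)}
                expected = set()
                for g in genes:
                    if g.chrom != nc.chrom:
                        continue
                    wbp = w * 1_000_000
                    if g.start < nc.end + wbp and g.end > nc.start - wbp:
                        expected.add(g.feature_id)
                assert hits == expected
                sets[w] = hits
            assert sets[1] <= sets[2] <= sets[3]


class TestNearest:
    def test_argmin_and_single(self):
        nc = GenomicInterval("chr1", 1_000_000, 1_010_000, feature_id="L1")
        g_near = GenomicInterval("chr1", 1_400_000, 1_410_000, feature_id="B")
        g_far = GenomicInterval("chr1", 1_810_000, 1_820_000, feature_id="A")
        hits = targets.prioritize_nearest(
            targets.find_window_targets(nc, [g_far, g_near], 1))
        nearest = [t for t in hits if t.is_nearest]
        assert len(nearest) == 1 and nearest[0].target_gene_id == "B"

    def test_tie_breaks_lexicographically(self):
        nc = GenomicInterval("chr1", 1_000_000, 1_010_000, feature_id="L1")
        left = GenomicInterval("chr1", 990_000, 999_000, feature_id="ZZ")
        right = GenomicInterval("chr1", 1_011_000, 1_020_000, feature_id="AA")
        hits = targets.prioritize_nearest(
            targets.find_window_targets(nc, [left, right], 1))
        nearest = [t for t in hits if t.is_nearest]
        assert len(nearest) == 1 and nearest[0].target_gene_id == "AA"

    def test_matches_sort_oracle(self, rng):
        feats = random_intervals(rng, 100, chroms=("chr1",))
        nc, genes = feats[0], feats[1:]
        hits = targets.prioritize_nearest(targets.find_window_targets(nc, genes, 3))
        if hits:
            best = min(hits, key=lambda t: (t.gap_bp, t.target_gene_id))
            assert [t.target_gene_id for t in hits if t.is_nearest] == [best.target_gene_id]


class TestRegulationClass:
    def test_examples(self):
        nc = GenomicInterval("chr1", 5_000_000, 5_010_000, feature_id="L")
        near = GenomicInterval("chr1", 5_400_000, 5_500_000, feature_id="G")
        other = GenomicInterval("chr2", 5_400_000, 5_500_000, feature_id="H")
        assert targets.classify_regulation(nc, near, 1) == "cis"
        assert targets.classify_regulation(nc, other, 1) == "trans"

    def test_window_sweep_never_flips_cis_to_trans(self, rng):
        feats = random_intervals(rng, 60, chroms=("chr1",))
        nc = feats[0]
        for g in feats[1:]:
            prev = None
            for w in (1, 2, 3):
                cls = targets.classify_regulation(nc, g, w)
                if prev == "cis":
                    assert cls == "cis"
                prev = cls


class TestPairwiseIdentity:
    def test_identical_is_one(self):
        assert targets.pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_planted_substitutions(self, rng):
        parent = "".join(rng.choice(list("ACGT"), size=200))
        mut, _ = simulate.make_pseudogene(parent, 0.85, rng)
        assert targets.pairwise_identity(parent, mut) == pytest.approx(0.85)

    def test_symmetric(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=30))
        b = "".join(rng.choice(list("ACGT"), size=25))
        assert targets.pairwise_identity(a, b) == pytest.approx(
            targets.pairwise_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            targets.pairwise_identity("", "ACGT")

    def test_score_matches_gotoh_dp(self, rng):
        """Alignment scores agree exactly with an independent affine-gap DP
        on random short pairs."""
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
            assert targets.alignment_score(a, b) == pytest.approx(
                gotoh_score(a, b), abs=1e-9)


class TestAssignParental:
    def make_family(self, rng, identity):
        parent = "".join(rng.choice(list("ACGT"), size=300))
        pseudo, realized = simulate.make_pseudogene(parent, identity, rng)
        return parent, pseudo, realized

    def reads(self, pid, unique=False, shared=True):
        rows = []
        if unique:
            rows.append(("r0", pid, 1, 0))
        if shared:
            rows.append(("r1", pid, 1, 1))
        return pd.DataFrame(rows, columns=["read_id", "pseudogene_id",
                                           "maps_pseudogene", "maps_parent"])

    def test_planted_family_low_identity_shared(self, rng):
        parent, pseudo, _ = self.make_family(rng, 0.85)
        decoy = "".join(rng.choice(list("ACGT"), size=300))
        out = targets.assign_parental({"P1": pseudo},
                                      {"PARA": parent, "PARB": decoy},
                                      self.reads("P1"))
        assert out[0].parental_id == "PARA"
        assert out[0].evidence == "shared_reads_low_identity"
        assert out[0].identity < 0.90

    def test_high_identity_shared_is_none(self, rng):
        parent, pseudo, _ = self.make_family(rng, 0.95)
        out = targets.assign_parental({"P1": pseudo}, {"PARA": parent},
                                      self.reads("P1"))
        assert out[0].evidence == "none"

    def test_unique_reads_evidence(self, rng):
        parent, pseudo, _ = self.make_family(rng, 0.95)
        out = targets.assign_parental({"P1": pseudo}, {"PARA": parent},
                                      self.reads("P1", unique=True))
        assert out[0].evidence == "unique_reads"

    def test_argmax_matches_allpairs_bruteforce(self, rng):
        parents = {f"PAR{i}": "".join(rng.choice(list("ACGT"), size=150))
                   for i in range(4)}
        pseudos = {}
        for i, (pid, pseq) in enumerate(parents.items()):
            pseudos[f"PSG{i}"], _ = simulate.make_pseudogene(pseq, 0.88, rng)
        out = targets.assign_parental(pseudos, parents, self.reads("PSG0"))
        for pa in out:
            scores = {cid: targets.alignment_score(pseudos[pa.pseudogene_id], cs)
                      for cid, cs in parents.items()}
            best = max(sorted(scores), key=lambda c: scores[c])
            assert pa.parental_id == best

    def test_missing_candidate_errors(self, rng):
        with pytest.raises(ValueError):
            targets.assign_parental({"P": "ACGT"}, {}, self.reads("P"))
        with pytest.raises(ValueError, match="candidate"):
            targets.assign_parental({"P": "ACGT"}, {"C": ""}, self.reads("P"))

    def test_full_recovery_on_simulated_families(self, sim_data):
        """100% parental recovery on the planted families, with correct
        evidence across the 0.90 identity boundary."""
        parents = {k: v for k, v in sim_data.pseudogene_seqs.items()
                   if k.startswith("PAR")}
        pseudos = {k: v for k, v in sim_data.pseudogene_seqs.items()
                   if k.startswith("PSG")}
        out = targets.assign_parental(pseudos, parents, sim_data.read_evidence)
        for pa in out:
            truth_parent, truth_ident = sim_data.truth.pseudogene_parent_map[
                pa.pseudogene_id]
            assert pa.parental_id == truth_parent
            if pa.evidence == "shared_reads_low_identity":
                assert pa.identity < 0.90
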