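"""Diversity statistics against brute-force oracles and hand computations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathsel import diversity_stats as ds
from pathsel.io_formats import MISSING, PopulationPartition

from conftest import make_alignment, random_alignment


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent)
# ---------------------------------------------------------------------------

def oracle_pi(alignment, subset=None):
    """Pairwise-deletion pi by explicit double loop over pairs and sites."""
    if subset is not None:
        alignment = alignment.subset(list(subset))
    seqs = alignment.sequences
    n = len(seqs)
    total, pairs = 0.0, 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    comparable += 1
                    diffs += a != b
            pairs += 1
            if comparable:
                total += diffs / comparable
    return total / pairs


def oracle_between_pi(aln, group_a, group_b):
    sa = aln.subset(group_a).sequences
    sb = aln.subset(group_b).sequences
    total, pairs = 0.0, 0
    for x in sa:
        for y in sb:
            comparable = diffs = 0
            for a, b in zip(x, y):
                if a in "ACGT" and b in "ACGT":
                    comparable += 1
                    diffs += a != b
            pairs += 1
            if comparable:
                total += diffs / comparable
    return total / pairs


class TestThetaPi:
    def test_single_difference_over_100_sites(self):
        a = "A" * 100
        b = "C" + "A" * 99
        assert ds.theta_pi(make_alignment([a, b])) == pytest.approx(0.01)

    def test_identical_sequences_zero(self):
        aln = make_alignment(["ACGT" * 5] * 4)
        assert ds.theta_pi(aln) == 0.0

    def test_matches_bruteforce_on_random_alignments(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 6))
            aln = random_alignment(rng, n, 60, missing_rate=0.1)
            assert ds.theta_pi(aln) == pytest.approx(oracle_pi(aln), abs=1e-12)

    def test_subset_smaller_than_two_rejected(self):
        aln = make_alignment(["AAAA", "CCCC"], ids=["a", "b"])
        with pytest.raises(ValueError):
            ds.theta_pi(aln, ["a"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 6), st.integers(4, 40))
    def test_property_matches_oracle(self, seed, n, length):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n, length, missing_rate=0.15)
        assert ds.theta_pi(aln) == pytest.approx(oracle_pi(aln), abs=1e-12)


class TestWattersonTheta:
    def test_two_sequences_one_difference(self):
        aln = make_alignment(["A" * 100, "C" + "A" * 99])
        assert ds.watterson_theta(aln) == pytest.approx(0.01)  # a_2 = 1

    def test_invariant_is_zero(self):
        assert ds.watterson_theta(make_alignment(["ACGT"] * 5)) == 0.0

    def test_hand_computed_harmonic_sum(self):
        # n=4, S=11, L=1000: a_4 = 1 + 1/2 + 1/3 = 11/6
        rng = np.random.default_rng(5)
        base = list("A" * 1000)
        seqs = [base[:] for _ in range(4)]
        sites = rng.choice(1000, size=11, replace=False)
        for k, site in enumerate(sites):
            seqs[k % 3 + 1][site] = "G"  # 11 segregating sites
        aln = make_alignment(["".join(s) for s in seqs])
        s, _ = ds.segregating_sites(aln)
        assert s == 11
        assert ds.watterson_theta(aln) == pytest.approx(11 / ((11 / 6) * 1000), rel=1e-12)

    def test_complete_deletion_shrinks_effective_length(self):
        aln = make_alignment(["AANA", "AANA", "CANA"])
        s, l_eff = ds.segregating_sites(aln)
        assert (s, l_eff) == (1, 3)
        assert ds.watterson_theta(aln) == pytest.approx(1 / (1.5 * 3))


class TestTajimasD:
    def test_invariant_marker(self):
        assert ds.tajimas_d(make_alignment(["ACGT"] * 6)) is None

    def test_all_singletons_negative(self):
        # n=10, S=5, every variant private to one sequence
        seqs = [list("A" * 50) for _ in range(10)]
        for k in range(5):
            seqs[k][k * 7] = "T"
        aln = make_alignment(["".join(s) for s in seqs])
        d = ds.tajimas_d(aln)
        assert d is not None and d < 0

    def test_direct_formula_evaluation(self):
        # hand evaluation for n=4, S=2, counts known exactly
        seqs = ["AAAA", "AAAT", "CAAA", "AAAA"]
        aln = make_alignment(seqs)
        n, s = 4, 2
        # mean pairwise difference count: pairs with diffs: each variant is a
        # singleton -> each contributes 3 of 6 pairs -> pi = (3+3)/6 = 1.0
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = (1.0 - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
        assert ds.tajimas_d(aln) == pytest.approx(expected, rel=1e-12)

    def test_rejects_single_sequence(self):
        aln = make_alignment(["AAAA", "CCCC"], ids=["a", "b"])
        with pytest.raises(ValueError):
            ds.tajimas_d(aln, ["a"])


class TestHudsonFst:
    def test_fixed_differences_give_one(self, two_group_partition):
        seqs = ["AAAA"] * 4 + ["TTTT"] * 4
        ids = [f"L{i}" for i in range(1, 5)] + [f"W{i}" for i in range(1, 5)]
        aln = make_alignment(seqs, ids=ids)
        assert ds.hudson_fst(aln, two_group_partition) == pytest.approx(1.0)

    def test_identical_sequences_exactly_zero(self, two_group_partition):
        # Hb == 0 (no between-group differences at all) is defined as FST = 0
        seqs = ["AAGT"] * 8
        ids = [f"L{i}" for i in range(1, 5)] + [f"W{i}" for i in range(1, 5)]
        aln = make_alignment(seqs, ids=ids)
        assert ds.hudson_fst(aln, two_group_partition) == 0.0

    def test_hand_built_hw_hb(self):
        # 2+2 sequences, L=1000: within pairs differ at 5 sites each
        # (Hw = 0.005), between pairs differ at 10 sites (Hb = 0.01) -> 0.5
        L = 1000
        base = "A" * L
        l1 = list(base); l2 = list(base)
        w1 = list(base); w2 = list(base)
        for i in range(5):
            l2[i] = "C"            # within-landrace: 5 diffs
        for i in range(5, 10):
            w2[i] = "C"            # within-wild: 5 diffs
        for i in range(100, 110):
            w1[i] = "G"; w2[i] = "G"  # fixed in wild: between += 10
        # between pairs: l1-w1: 10; l1-w2: 5+10=15; l2-w1: 5+10=15; l2-w2: 5+5+10=20
        # -> Hb = (10+15+15+20)/4/L = 0.015; Hw = 0.005 -> FST = 1 - 1/3
        aln = make_alignment(
            ["".join(x) for x in (l1, l2, w1, w2)], ids=["L1", "L2", "W1", "W2"])
        part = PopulationPartition({"L1": "landrace", "L2": "landrace",
                                    "W1": "wild", "W2": "wild"})
        assert ds.hudson_fst(aln, part) == pytest.approx(1 - 0.005 / 0.015, rel=1e-12)

    def test_matches_bruteforce_between_pi(self, rng, two_group_partition):
        for _ in range(20):
            aln = random_alignment(rng, 8, 40, missing_rate=0.1)
            aln.sample_ids = [f"L{i}" for i in range(1, 5)] + [f"W{i}" for i in range(1, 5)]
            land = [f"L{i}" for i in range(1, 5)]
            wild = [f"W{i}" for i in range(1, 5)]
            hw = 0.5 * (oracle_pi(aln, land) + oracle_pi(aln, wild))
            hb = oracle_between_pi(aln, land, wild)
            expected = 0.0 if hb == 0 else 1 - hw / hb
            assert ds.hudson_fst(aln, two_group_partition) == pytest.approx(expected, abs=1e-12)

    def test_panmixia_straddles_zero(self, rng, two_group_partition):
        ids = [f"L{i}" for i in range(1, 5)] + [f"W{i}" for i in range(1, 5)]
        vals = []
        for _ in range(200):
            aln = random_alignment(rng, 8, 30)
            aln.sample_ids = list(ids)
            vals.append(ds.hudson_fst(aln, two_group_partition))
        vals = np.array(vals)
        assert (vals < 0).any() and (vals > 0).any()
        assert abs(np.mean(vals)) < 0.05

    def test_missing_group_rejected(self, two_group_partition):
        aln = make_alignment(["AAAA"] * 4, ids=[f"L{i}" for i in range(1, 5)])
        with pytest.raises(ValueError, match="wild"):
            ds.hudson_fst(aln, two_group_partition)


class TestCodonStats:
    @pytest.fixture
    def partition(self):
        return PopulationPartition(
            {**{f"L{i}": "landrace" for i in range(1, 4)},
             **{f"W{i}": "wild" for i in range(1, 4)}})

    def _aln(self, land_codons, wild_codons):
        ids = [f"L{i}" for i in range(1, 4)] + [f"W{i}" for i in range(1, 4)]
        return make_alignment(land_codons + wild_codons, ids=ids)

    def test_monomorphic_codon(self, partition):
        aln = self._aln(["ATGGGG"] * 3, ["ATGGGG"] * 3)
        track = ds.codon_stats(aln, partition)
        assert track.effect == ["monomorphic", "monomorphic"]
        assert np.isnan(track.tajimas_d).all()
        assert (track.fst == 0).all()

    def test_synonymous_codon_ggg_gga(self, partition):
        aln = self._aln(["ATGGGG", "ATGGGA", "ATGGGG"], ["ATGGGG"] * 3)
        track = ds.codon_stats(aln, partition)
        assert track.effect[1] == "synonymous"

    def test_nonsynonymous_codon(self, partition):
        aln = self._aln(["ATGAAA", "ATGGAA", "ATGAAA"], ["ATGAAA"] * 3)  # Lys -> Glu
        track = ds.codon_stats(aln, partition)
        assert track.effect[1] == "nonsynonymous"

    def test_two_segregating_sites_complex_and_pi_additive(self, partition):
        land = ["ATGGGG", "ATGAGA", "ATGGGA"]
        wild = ["ATGGGG"] * 3
        aln = self._aln(land, wild)
        track = ds.codon_stats(aln, partition)
        assert track.effect[1] == "complex"
        # per-codon pi equals the single-site oracle applied to the window
        window = make_alignment([s[3:6] for s in land])
        assert track.pi_landrace[1] == pytest.approx(oracle_pi(window), abs=1e-12)

    def test_codon_diff_sum_matches_gene_level(self, rng, partition):
        # complete-deletion pairwise counts are conserved across the codon split
        aln = random_alignment(rng, 6, 30)
        aln.sample_ids = [f"L{i}" for i in range(1, 4)] + [f"W{i}" for i in range(1, 4)]
        track = ds.codon_stats(aln, partition)
        land = aln.subset([f"L{i}" for i in range(1, 4)])
        gene_pi_sum = sum(
            track.pi_landrace[c] * 3 for c in range(track.n_codons))
        assert gene_pi_sum == pytest.approx(ds.theta_pi(land) * 30, abs=1e-9)


class TestHarmonicNumber:
    def test_values(self):
        assert ds.harmonic_number(2) == 1.0
        assert ds.harmonic_number(4) == pytest.approx(11 / 6)
        assert ds.harmonic_number(4, 2) == pytest.approx(1 + 1 / 4 + 1 / 9)
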