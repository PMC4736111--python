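import numpy as np
import pandas as pd
import pytest

from ldscape import ldcore
from conftest import make_haps, random_polymorphic_haps

# Per-chromosome SNP counts of a 29-autosome, 41,207-marker array layout
# (used as the ceiling-arithmetic oracle for adjacent-pair and thinning counts)
CHROM_SNP_COUNTS = [
    2697, 2197, 2000, 1987, 1732, 2066, 1824, 1958, 1670, 1760,
    1805, 1342, 1449, 1471, 1374, 1314, 1249, 1036, 1058, 1264,
    1124, 1021, 838, 1014, 753, 867, 763, 747, 827,
]


def haps_from_counts(counts, spacing=61_000, n_gametes=4, seed=0):
    rng = np.random.default_rng(seed)
    chroms, positions = [], []
    for c, n in enumerate(counts, start=1):
        chroms += [str(c)] * n
        positions += [spacing * (i + 1) for i in range(n)]
    m = len(chroms)
    # alternate alleles guarantee polymorphism with 4 gametes
    H = rng.integers(0, 2, size=(n_gametes, m), dtype=np.uint8)
    H[0] = 0
    H[1] = 1
    return make_haps(H, chroms=chroms, positions=positions)


class TestPairLD:
    def test_complete_coupling(self):
        a = np.array([1, 1, 0, 0, 1, 0])
        r, r2 = ldcore.pair_ld(a, a)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independence(self):
        # all four haplotypes at frequency 1/4
        a = np.array([1, 1, 0, 0])
        b = np.array([1, 0, 1, 0])
        r, r2 = ldcore.pair_ld(a, b)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_hand_counted_ten_gametes(self):
        # 4xA1B1, 1xA1B2, 2xA2B1, 3xA2B2: D = 0.4 - 0.5*0.6 = 0.10
        a = np.array([1] * 4 + [1] + [0] * 2 + [0] * 3)
        b = np.array([1] * 4 + [0] + [1] * 2 + [0] * 3)
        r, r2 = ldcore.pair_ld(a, b)
        assert r == pytest.approx(0.10 / np.sqrt(0.25 * 0.24), rel=1e-12)
        assert r2 == pytest.approx(1.0 / 6.0, rel=1e-12)
        # equals squared Pearson correlation of the 0/1 indicators
        assert r == pytest.approx(np.corrcoef(a, b)[0, 1], rel=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="undefined LD"):
            ldcore.pair_ld(np.ones(6), np.array([1, 0, 1, 0, 1, 0]))

    def test_equals_pearson_on_random_fixtures(self, rng):
        """Haplotype-frequency formula == squared Pearson correlation of
        allele indicators, to 1e-12, over many random gamete sets."""
        for _ in range(300):
            n = int(rng.integers(4, 51))
            h = random_polymorphic_haps(rng, n, 2)
            a, b = h.haplotypes[:, 0], h.haplotypes[:, 1]
            r, r2 = ldcore.pair_ld(a, b)
            rp = np.corrcoef(a, b)[0, 1]
            assert abs(r - rp) < 1e-12
            assert abs(r2 - rp * rp) < 1e-12

    def test_label_swap_symmetry(self, rng):
        h = random_polymorphic_haps(rng, 20, 2)
        a, b = h.haplotypes[:, 0], h.haplotypes[:, 1]
        r, r2 = ldcore.pair_ld(a, b)
        r_swapped, r2_swapped = ldcore.pair_ld(1 - a, b)
        assert r_swapped == pytest.approx(-r, rel=1e-12)
        assert r2_swapped == pytest.approx(r2, rel=1e-12)
        r_both, _ = ldcore.pair_ld(1 - a, 1 - b)
        assert r_both == pytest.approx(r, rel=1e-12)

    def test_gamete_permutation_invariance(self, rng):
        h = random_polymorphic_haps(rng, 30, 2)
        a, b = h.haplotypes[:, 0], h.haplotypes[:, 1]
        perm = rng.permutation(30)
        assert ldcore.pair_ld(a, b) == pytest.approx(ldcore.pair_ld(a[perm], b[perm]))


class TestSyntenicPairs:
    def test_pair_count_unlimited(self, rng):
        h = random_polymorphic_haps(rng, 10, 3)
        assert len(ldcore.syntenic_pairs(h, None)) == 3  # C(3,2)

    def test_distance_cap(self, rng):
        h = random_polymorphic_haps(
            rng, 10, 3, positions=[100_000, 200_000, 11_000_000]
        )
        pairs = ldcore.syntenic_pairs(h, 10_000_000)
        assert len(pairs) == 1
        assert pairs.iloc[0]["distance_bp"] == 100_000

    def test_no_cross_chromosome_pairs(self, rng):
        h = random_polymorphic_haps(
            rng, 10, 4, chroms=["1", "1", "2", "2"], positions=[1, 2, 1, 2]
        )
        pairs = ldcore.syntenic_pairs(h, None)
        assert len(pairs) == 2
        assert set(pairs["chrom"]) == {"1", "2"}

    def test_matches_pair_ld(self, rng):
        h = random_polymorphic_haps(rng, 24, 6)
        pairs = ldcore.syntenic_pairs(h, None)
        for _, row in pairs.iterrows():
            i = list(h.map.pos_bp).index(row["pos_i"])
            j = list(h.map.pos_bp).index(row["pos_j"])
            r, r2 = ldcore.pair_ld(h.haplotypes[:, i], h.haplotypes[:, j])
            assert row["r_signed"] == pytest.approx(r, abs=1e-12)
            assert row["r2"] == pytest.approx(r2, abs=1e-12)

    def test_r2_is_square_of_r(self, rng):
        h = random_polymorphic_haps(rng, 40, 12)
        pairs = ldcore.syntenic_pairs(h, None)
        assert np.allclose(pairs["r2"], pairs["r_signed"] ** 2, atol=1e-12)


class TestAdjacentPairs:
    def test_array_layout_pair_count(self):
        """Sum over chromosomes of (n_i - 1) for the 41,207-marker layout."""
        h = haps_from_counts(CHROM_SNP_COUNTS)
        assert sum(CHROM_SNP_COUNTS) == 41_207
        ap = ldcore.adjacent_pairs(h)
        assert len(ap) == sum(n - 1 for n in CHROM_SNP_COUNTS) == 41_178

    def test_single_marker_chromosome_contributes_none(self, rng):
        h = random_polymorphic_haps(
            rng, 10, 3, chroms=["1", "1", "2"], positions=[1, 2, 1]
        )
        assert len(ldcore.adjacent_pairs(h)) == 1

    def test_five_markers_four_pairs(self, rng):
        h = random_polymorphic_haps(rng, 10, 5)
        assert len(ldcore.adjacent_pairs(h)) == 4


class TestBinning:
    def test_all_in_one_bin(self, rng):
        pairs = pd.DataFrame(
            {"chrom": "1", "pos_i": 0, "pos_j": 0, "distance_bp": [150_000] * 5,
             "r_signed": 0.5, "r2": [0.4] * 5}
        )
        bins = ldcore.bin_by_distance(pairs)
        assert bins.loc[1, "n_pairs"] == 5
        assert bins.loc[1, "mean_r2"] == pytest.approx(0.4)
        assert bins.loc[1, "sd_r2"] == pytest.approx(0.0)
        assert bins["n_pairs"].sum() == 5

    def test_boundary_pair_goes_to_upper_bin(self):
        pairs = pd.DataFrame(
            {"chrom": "1", "pos_i": 0, "pos_j": 0, "distance_bp": [100_000],
             "r_signed": 0.1, "r2": [0.01]}
        )
        bins = ldcore.bin_by_distance(pairs)
        assert bins.loc[0, "n_pairs"] == 0
        assert bins.loc[1, "n_pairs"] == 1

    def test_partition_property(self, rng):
        d = rng.integers(1, 10_000_000, 500)
        pairs = pd.DataFrame(
            {"chrom": "1", "pos_i": 0, "pos_j": 0, "distance_bp": d,
             "r_signed": 0.0, "r2": rng.random(500)}
        )
        bins = ldcore.bin_by_distance(pairs)
        assert bins["n_pairs"].sum() == (d < 10_000_000).sum()
        assert len(bins) == 100

    def test_empty_bins_reported(self):
        pairs = pd.DataFrame(columns=["chrom", "pos_i", "pos_j", "distance_bp", "r_signed", "r2"])
        bins = ldcore.bin_by_distance(pairs)
        assert (bins["n_pairs"] == 0).all()
        assert bins["mean_r2"].isna().all()


class TestProportionAbove:
    @pytest.mark.parametrize(
        "r2vals,thr,expect",
        [([0.5, 0.5, 0.5], 0.2, 1.0), ([0.1, 0.3], 0.2, 0.5), ([0.2, 0.9], 1.0, 0.0)],
    )
    def test_values(self, r2vals, thr, expect):
        pairs = pd.DataFrame({"r2": r2vals})
        assert ldcore.proportion_above(pairs, thr) == pytest.approx(expect)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ldcore.proportion_above(pd.DataFrame({"r2": []}), 0.2)


class TestThinning:
    def test_identity(self, rng):
        h = random_polymorphic_haps(rng, 10, 8)
        assert ldcore.thin_panel(h, 1) == h

    def test_every_second(self, rng):
        h = random_polymorphic_haps(rng, 10, 10)
        hk = ldcore.thin_panel(h, 2)
        assert hk.n_markers == 5
        assert list(hk.map.pos_bp) == list(h.map.pos_bp[0::2])

    def test_array_layout_ceiling_arithmetic(self):
        """keep_every=5 retains per-chromosome ceil(n_i/5) markers."""
        h = haps_from_counts(CHROM_SNP_COUNTS)
        hk = ldcore.thin_panel(h, 5)
        expected = sum(int(np.ceil(n / 5)) for n in CHROM_SNP_COUNTS)
        assert hk.n_markers == expected
        assert abs(expected - 8241) <= 29

    def test_restart_per_chromosome(self, rng):
        h = random_polymorphic_haps(
            rng, 10, 6, chroms=["1"] * 3 + ["2"] * 3, positions=[1, 2, 3, 1, 2, 3]
        )
        hk = ldcore.thin_panel(h, 3)
        # first marker of each chromosome retained
        assert list(hk.map.pos_bp) == [1, 1]

    def test_excessive_keep_every_rejected(self, rng):
        h = random_polymorphic_haps(rng, 10, 4)
        with pytest.raises(ValueError, match="keep_every"):
            ldcore.thin_panel(h, 5)

    def test_experiment_first_row_equals_full_panel(self, rng):
        h = random_polymorphic_haps(rng, 40, 30)
        tab = ldcore.thinning_experiment(h, [1, 2])
        ap = ldcore.adjacent_pairs(h)
        assert tab.loc[0, "mean_r2"] == pytest.approx(ap["r2"].mean())
        assert tab.loc[0, "n_markers"] == 30

    def test_experiment_distance_scales_with_thinning(self, rng):
        # evenly spaced markers: mean adjacent distance ~ keep_every x spacing
        h = random_polymorphic_haps(
            rng, 40, 60, positions=[50_000 * (i + 1) for i in range(60)]
        )
        tab = ldcore.thinning_experiment(h, [1, 2, 4])
        base = tab.loc[0, "mean_distance_kb"]
        assert tab.loc[1, "mean_distance_kb"] == pytest.approx(2 * base, rel=0.05)
        assert tab.loc[2, "mean_distance_kb"] == pytest.approx(4 * base, rel=0.10)
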