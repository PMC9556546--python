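"""Tests of interference statistics: distances, permutation null, CoC."""

import itertools

import numpy as np
import pandas as pd
import pytest

import meiocross as mx
from meiocross import configs


def table_from(rows):
    return mx.make_crossover_table(rows)


@pytest.fixture
def one_chrom():
    return mx.Karyotype((mx.Chromosome("chr1", 24.0, 30.0),))


class TestTwoCODistances:
    def test_simple_distance(self):
        t = table_from([("s1", "chr1", 5.0), ("s1", "chr1", 25.0)])
        d = mx.two_co_distances(t)
        assert d["chr1"].tolist() == [20.0]

    def test_only_exactly_two_contribute(self):
        t = table_from(
            [("s1", "chr1", 5.0)]
            + [("s2", "chr1", p) for p in (1.0, 2.0, 3.0)]
            + [("s3", "chr1", 4.0), ("s3", "chr1", 9.0)]
        )
        d = mx.two_co_distances(t)
        assert d["chr1"].tolist() == [5.0]

    def test_uniform_null_mean_is_L_over_3(self, one_chrom, params, rng):
        g = mx.GenotypeSpec(
            name="z", zyp1=True, poisson_means={"chr1": 2.0}, sex="female"
        )
        _, t = mx.simulate_population(g, one_chrom, 6000, params, rng)
        d = mx.two_co_distances(t)["chr1"]
        assert d.mean() == pytest.approx(10.0, abs=0.35)


class TestPermutationNull:
    def test_enumerated_cross_pairs(self, rng):
        # every sample has COs exactly at 10 and 20 Mb -> null distances in {0, 10}
        rows = []
        for s in range(6):
            rows += [(f"s{s}", "chr1", 10.0), (f"s{s}", "chr1", 20.0)]
        null = mx.permutation_null(table_from(rows), rng)
        assert set(np.unique(null.distances["chr1"])) <= {0.0, 10.0}

    def test_single_sample_contributes_own_pair(self, rng):
        t = table_from([("s1", "chr1", 3.0), ("s1", "chr1", 8.0)])
        null = mx.permutation_null(t, rng)
        assert null.distances["chr1"].tolist() == [5.0]

    def test_no_eligible_samples_raises(self, rng):
        t = table_from([("s1", "chr1", 3.0)])
        with pytest.raises(ValueError):
            mx.permutation_null(t, rng)

    def test_chromosome_shares_match_observation(self, rng):
        rows = []
        for s in range(30):  # 30 two-CO samples on chr1, 10 on chr2
            rows += [(f"a{s}", "chr1", 1.0 + s * 0.1), (f"a{s}", "chr1", 20.0 + s * 0.1)]
        for s in range(10):
            rows += [(f"b{s}", "chr2", 2.0 + s * 0.1), (f"b{s}", "chr2", 9.0 + s * 0.1)]
        null = mx.permutation_null(table_from(rows), rng)
        share = null.downsampled_to["chr1"] / len(null)
        assert share == pytest.approx(0.75, abs=0.02)

    def test_null_is_interference_free(self, one_chrom, params, rng):
        # data drawn from the null model are not distinguished from the null
        g = mx.GenotypeSpec(name="z", zyp1=True, poisson_means={"chr1": 2.0})
        _, t = mx.simulate_population(g, one_chrom, 800, params, rng)
        obs = np.concatenate(list(mx.two_co_distances(t).values()))
        null = mx.permutation_null(t, rng)
        p = mx.compare_distance_distributions(obs, null)
        assert p > 0.01


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        assert mx.compare_distance_distributions(x, x.copy()) == pytest.approx(1.0)

    def test_strong_shift_detected(self, rng):
        a = rng.uniform(0, 10, 100)
        b = rng.uniform(0, 10, 100) + 15.0
        assert mx.compare_distance_distributions(a, b) < 1e-3

    def test_small_sample_matches_exhaustive_enumeration(self):
        # n1 = n2 = 3, no ties: enumerate all C(6,3)=20 rank assignments
        x = np.array([1.0, 4.0, 6.0])
        y = np.array([2.0, 3.0, 5.0])
        p_impl = mx.compare_distance_distributions(x, y)
        pooled = np.concatenate([x, y])
        u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        us = []
        for idx in itertools.combinations(range(6), 3):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(6) if i not in idx]]
            us.append(sum(1 for a in xs for b in ys if a > b))
        us = np.array(us)
        mu = len(x) * len(y) / 2
        p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
        assert p_impl == pytest.approx(p_exact)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mx.compare_distance_distributions(np.array([]), np.array([1.0]))


class TestCoCCurve:
    def test_hand_computed_fixture(self, one_chrom):
        # 4 chromatids on a 30 Mb chromosome with 3 intervals of 10 Mb:
        #   s1: COs in intervals 0 and 1; s2: interval 0; s3: intervals 0,2; s4: none on i>0
        rows = [
            ("s1", "chr1", 2.0), ("s1", "chr1", 12.0),
            ("s2", "chr1", 3.0),
            ("s3", "chr1", 4.0), ("s3", "chr1", 25.0),
            ("s4", "chr1", 5.0),
        ]
        curve = mx.coc_curve(table_from(rows), one_chrom, n_intervals=3)
        # f0 = 1.0, f1 = 0.25, f2 = 0.25; f01 = 0.25, f02 = 0.25, f12 = 0
        by_pair = {
            (r.interval_i, r.interval_j): r.coc for r in curve.pairs.itertuples()
        }
        assert by_pair[(0, 1)] == pytest.approx(0.25 / (1.0 * 0.25))
        assert by_pair[(0, 2)] == pytest.approx(0.25 / (1.0 * 0.25))
        assert by_pair[(1, 2)] == pytest.approx(0.0)

    def test_single_co_per_chromatid_gives_zero(self, one_chrom):
        rows = [(f"s{k}", "chr1", 1.0 + 28.0 * k / 39) for k in range(40)]
        curve = mx.coc_curve(table_from(rows), one_chrom, n_intervals=13)
        assert curve.pairs["coc"].max() == 0.0

    def test_independent_placement_calibrates_to_one(self, one_chrom, params, rng):
        g = mx.GenotypeSpec(name="z", zyp1=True, poisson_means={"chr1": 3.0})
        _, t = mx.simulate_population(g, one_chrom, 10_000, params, rng)
        curve = mx.coc_curve(t, one_chrom, n_intervals=13, n_samples=10_000)
        assert curve.mean_coc == pytest.approx(1.0, abs=0.05)

    def test_chromosome_exclusion_respected(self, karyotype, params, rng):
        g = configs.genotype_preset("zyp1_hybrid", "female", karyotype)
        _, t = mx.simulate_population(g, karyotype, 500, params, rng)
        curve = mx.coc_curve(t, karyotype, exclude=("chr4",), n_samples=500)
        assert "chr4" not in set(curve.pairs["chromosome"])

    def test_row_order_invariance(self, one_chrom, rng):
        rows = [("s%d" % k, "chr1", float(p)) for k in range(30) for p in rng.uniform(0, 30, 2)]
        t = table_from(rows)
        shuffled = t.sample(frac=1, random_state=3).reset_index(drop=True)
        a = mx.coc_curve(t, one_chrom)
        b = mx.coc_curve(shuffled, one_chrom)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)


class TestCountSummaries:
    def test_perfect_proportionality_gives_r_one(self, karyotype):
        rows = []
        for s in range(4):
            for chrom in karyotype:
                for k in range(int(chrom.genomic_length_mb // 10) + 1):
                    rows.append((f"s{s}", chrom.name, 1.0 + k))
        s = mx.co_count_summaries(mx.make_crossover_table(rows), karyotype)
        assert s.length_correlation == pytest.approx(1.0, abs=0.05)

    def test_single_sample_total(self, karyotype):
        t = table_from([("s1", "chr1", 1.0), ("s1", "chr2", 2.0), ("s1", "chr2", 3.0)])
        s = mx.co_count_summaries(t, karyotype)
        assert s.per_sample_total["s1"] == 3

    def test_few_chromosomes_flagged_unreliable(self):
        kt = mx.Karyotype((mx.Chromosome("c1", 10, 20), mx.Chromosome("c2", 8, 15)))
        t = table_from([("s1", "c1", 1.0), ("s2", "c2", 2.0), ("s1", "c2", 3.0)])
        s = mx.co_count_summaries(t, kt)
        assert not s.length_correlation_reliable


class TestDensityProfile:
    def test_flat_for_uniform_placement(self, one_chrom, rng):
        rows = [(f"s{k}", "chr1", float(p)) for k in range(200) for p in rng.uniform(0, 30, 3)]
        prof = mx.co_density_profile(table_from(rows), one_chrom)
        inner = prof[(prof["start_bp"] >= 1_000_000) & (prof["end_bp"] <= 29_000_000)]
        expect = 3 / 30  # 3 COs per sample over 30 Mb, 1 Mb windows
        assert inner["density"].mean() == pytest.approx(expect, rel=0.1)
        assert inner["density"].std() < expect

    def test_point_mass_spans_twenty_windows(self, one_chrom):
        t = table_from([("s1", "chr1", 15.0)])
        prof = mx.co_density_profile(t, one_chrom)
        assert (prof["density"] > 0).sum() == 20  # 1 Mb window / 50 kb step

    def test_empty_table_all_zero(self, one_chrom):
        t = mx.make_crossover_table([])
        prof = mx.co_density_profile(t, one_chrom)
        assert (prof["density"] == 0).all()

    def test_invalid_window_rejected(self, one_chrom):
        with pytest.raises(ValueError):
            mx.co_density_profile(mx.make_crossover_table([]), one_chrom, window_mb=0)
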