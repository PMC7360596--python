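"""Tajima's D: constants, windows, depth filters and beta significance."""

from fractions import Fraction

import numpy as np
import pytest

from supergene.simulate import SimulationConfig, simulate_genotype_matrix
from supergene.tajima import (GenotypeMatrix, depth_filter, segment_summary,
                              significance, tajima_constants, tajimas_d,
                              windowed_scan)


def _matrix(positions, genotypes, depths=None, groups=None, length=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if depths is None:
        depths = np.full(genotypes.shape, 10)
    samples = [f"s{i}" for i in range(genotypes.shape[1])]
    return GenotypeMatrix("chr16", np.asarray(positions), samples, genotypes,
                          np.asarray(depths), groups or {}, length)


def independent_constants(n):
    """Exact-rational re-derivation of the constants (test oracle)."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {k: float(v) for k, v in
            dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1,
                 e2=e2).items()}


class TestFormula:
    def test_constants_match_exact_rationals_for_n_4_to_50(self):
        for n in range(4, 51):
            mine = tajima_constants(n)
            oracle = independent_constants(n)
            for key, val in oracle.items():
                assert mine[key] == pytest.approx(val, abs=1e-9), (n, key)

    def test_zero_when_pi_equals_watterson(self):
        k = tajima_constants(10)
        S = 12
        assert tajimas_d(10, S, S / k["a1"]) == pytest.approx(0.0, abs=1e-12)

    def test_known_value_three_singletons_n4(self):
        # n=4, S=3 singleton sites: pi = 3 * 2*1*3/(4*3) = 1.5; direct
        # evaluation of the formula gives ~ -0.7544
        assert tajimas_d(4, 3, 1.5) == pytest.approx(-0.7544, abs=5e-4)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            tajimas_d(4, 0, 0.0)
        with pytest.raises(ValueError):
            tajimas_d(1, 3, 1.0)


class TestDepthFilter:
    def test_all_at_threshold_kept_in_both_modes(self):
        m = _matrix([10, 20], [[0, 1, 0], [1, 0, 0]],
                    depths=np.full((2, 3), 6))
        assert depth_filter(m, "whole_genome").n_sites == 2
        assert depth_filter(m, "rad").n_sites == 2

    def test_one_low_individual_kept_wg_dropped_rad(self):
        depths = np.array([[6, 6, 5], [6, 6, 6]])
        m = _matrix([10, 20], [[0, 1, 0], [1, 0, 0]], depths=depths)
        assert depth_filter(m, "whole_genome").n_sites == 2
        assert list(depth_filter(m, "rad").positions) == [20]

    def test_two_low_individuals_dropped_in_both(self):
        depths = np.array([[5, 6, 5], [6, 6, 6]])
        m = _matrix([10, 20], [[0, 1, 0], [1, 0, 0]], depths=depths)
        assert list(depth_filter(m, "whole_genome").positions) == [20]
        assert list(depth_filter(m, "rad").positions) == [20]

    def test_unknown_mode(self):
        m = _matrix([10], [[0, 1]])
        with pytest.raises(ValueError):
            depth_filter(m, "nope")


class TestWindowedScan:
    def test_empty_window_undefined(self):
        m = _matrix([], np.zeros((0, 4)), depths=np.zeros((0, 4)),
                    length=200_000)
        stats = windowed_scan(m, 100_000)
        assert len(stats) == 2
        assert all(w.S == 0 and not w.defined and w.p_flag == "undefined"
                   for w in stats)

    def test_all_snps_in_one_window(self):
        geno = [[0, 1, 0, 0], [0, 1, 1, 0], [1, 0, 0, 0]]
        m = _matrix([5, 50, 99], geno, length=300)
        stats = windowed_scan(m, 100)
        assert stats[0].S == 3 and stats[0].defined
        assert all(not w.defined for w in stats[1:])

    def test_tiling_identity(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 400_001), 300, replace=False))
        geno = rng.integers(0, 2, (300, 5))
        geno[:, 0] = 0  # keep sites polymorphic-but-not-fixed plausible
        m = _matrix(pos, geno, length=400_000)
        whole = windowed_scan(m, 100_000)
        lo = _matrix(pos[pos <= 200_000], geno[pos <= 200_000],
                     depths=np.full((int((pos <= 200_000).sum()), 5), 10),
                     length=200_000)
        first_half = windowed_scan(lo, 100_000)
        for a, b in zip(whole[:2], first_half):
            assert (a.S, a.pi) == (b.S, b.pi)
            assert (a.D == b.D) or (not a.defined and not b.defined)

    def test_listwise_missing_drop(self):
        geno = [[0, 1, -1], [0, 1, 0]]
        m = _matrix([10, 20], geno, length=100)
        (w,) = windowed_scan(m, 100)
        assert w.S == 1  # site with the missing call is dropped

    def test_pi_is_mean_pairwise_difference(self):
        # 4 haplotypes, one site with two carriers: 4 of 6 pairs differ
        m = _matrix([10], [[0, 0, 1, 1]], length=100)
        (w,) = windowed_scan(m, 100)
        assert w.pi == pytest.approx(4 / 6)

    def test_invalid_window(self):
        m = _matrix([10], [[0, 1]])
        with pytest.raises(ValueError):
            windowed_scan(m, 0)


class TestSignificance:
    def test_zero_is_ns(self):
        assert significance(0.0, 7) == "ns"

    def test_beyond_support_bounds(self):
        assert significance(-5.0, 7) == "significantly_negative"
        assert significance(9.0, 7) == "significantly_positive"

    def test_small_n_undefined(self):
        assert significance(-1.0, 3) == "undefined"

    def test_moderate_values_not_flagged(self):
        assert significance(-1.0, 7) == "ns"
        assert significance(1.0, 7) == "ns"


class TestSegmentSummary:
    def _stats(self):
        m = _matrix([], np.zeros((0, 4)), depths=np.zeros((0, 4)))
        from supergene.tajima import WindowStat
        mk = lambda s, D, flag: WindowStat("chr16", s, s + 99_999, 6, 5, 1.0,
                                           D, flag)
        return [mk(1, -1.0, "ns"), mk(100_001, -2.5, "significantly_negative"),
                mk(200_001, 0.5, "ns"), mk(300_001, float("nan"), "undefined")]

    def test_counts_match_hand_tally(self):
        seg = segment_summary(self._stats(), (1, 400_000))
        assert seg["n_windows"] == 4 and seg["n_defined"] == 3
        assert seg["mean_D"] == pytest.approx((-1.0 - 2.5 + 0.5) / 3)
        assert seg["n_negative"] == 2
        assert seg["n_significant_negative"] == 1
        assert seg["n_positive"] == 1 and seg["n_significant_positive"] == 0

    def test_undefined_only_segment(self):
        seg = segment_summary(self._stats(), (300_001, 400_000))
        assert np.isnan(seg["mean_D"]) and seg["n_negative"] == 0

    def test_empty_segment_raises(self):
        with pytest.raises(ValueError):
            segment_summary(self._stats(), (900_000, 950_000))


class TestSimulationBehaviour:
    def test_neutral_group_mean_d_near_zero(self):
        ds = []
        for seed in range(60):
            cfg = SimulationConfig(
                chrom_length_bp=100_000,
                genotype_groups={"g": (7, "neutral")}, seed=7000 + seed)
            gm = simulate_genotype_matrix(cfg)
            (w,) = windowed_scan(gm, 100_000)
            if w.defined:
                ds.append(w.D)
        assert abs(np.mean(ds)) < 0.35  # tighter bound in the full check

    def test_bottleneck_group_skews_negative(self):
        cfg = SimulationConfig(
            chrom_length_bp=1_000_000,
            genotype_groups={"neutral_g": (6, "neutral"),
                             "bottle_g": (6, "bottleneck")}, seed=42)
        gm = simulate_genotype_matrix(cfg)
        neu = windowed_scan(gm.subset_group("neutral_g"), 100_000,
                            chrom_length_bp=1_000_000)
        bot = windowed_scan(gm.subset_group("bottle_g"), 100_000,
                            chrom_length_bp=1_000_000)
        sn = segment_summary(neu, (1, 1_000_000))
        sb = segment_summary(bot, (1, 1_000_000))
        assert sb["mean_D"] < 0
        assert sb["n_significant_negative"] > sn["n_significant_negative"]
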