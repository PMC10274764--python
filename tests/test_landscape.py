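"""Trisomy-origin classification, eCDFs, and the permutation KS test."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from ldchase.landscape import (
    CrossoverDistribution,
    MeioticErrorCall,
    TractRegion,
    TractTrack,
    classify_error,
    ks_permutation,
    ks_statistic,
    label_region,
    pericentromeric_interval,
)

L = 100_000_000
CENT = (48_000_000, 52_000_000)


def track_from(regions, coverage=1.0, centromere=CENT, acrocentric=False):
    return TractTrack(
        chrom="chr1",
        chrom_length=L,
        centromere=centromere,
        acrocentric=acrocentric,
        regions=tuple(TractRegion(*r) for r in regions),
        coverage=coverage,
    )


class TestLabels:
    @pytest.mark.parametrize(
        "z,expected", [(2.5, "BPH"), (-2.5, "SPH"), (0.0, "ambiguous"), (1.96, "ambiguous")]
    )
    def test_threshold_labels(self, z, expected):
        assert label_region(z) == expected


class TestPericentromere:
    def test_centered_twenty_percent(self):
        lo, hi = pericentromeric_interval(L, (49_000_000, 51_000_000))
        assert (lo, hi) == (40_000_000, 60_000_000)

    def test_acrocentric_q_arm_only(self):
        lo, hi = pericentromeric_interval(L, (12_000_000, 15_000_000), acrocentric=True)
        assert (lo, hi) == (15_000_000, 25_000_000)

    def test_clipped_at_chromosome_start(self):
        lo, hi = pericentromeric_interval(L, (4_000_000, 6_000_000))
        assert lo == 0
        assert hi == 15_000_000


class TestClassifyError:
    def test_pericentromeric_bph_is_mi(self):
        # BPH over 60% of the chromosome including the whole pericentromere
        track = track_from([(20_000_000, 80_000_000, 3.0)])
        call = classify_error(track)
        assert call.call == "MI"
        assert call.bph_fraction == pytest.approx(0.6)
        assert call.peri_bph_fraction == pytest.approx(1.0)

    def test_distal_bph_with_pericentromeric_sph_is_mii(self):
        track = track_from(
            [(0, 15_000_000, 3.0), (35_000_000, 65_000_000, -3.0)]
        )
        call = classify_error(track)
        assert call.call == "MII"
        assert call.bph_fraction == pytest.approx(0.15)

    def test_chromosome_wide_sph_is_mitotic(self):
        track = track_from([(0, L, -3.0)])
        assert classify_error(track).call == "mitotic"

    def test_weak_signals_ambiguous(self):
        track = track_from(
            [(0, 5_000_000, 3.0), (10_000_000, 40_000_000, -3.0)]
        )
        # BPH 5% < 10%, SPH 30% < 50%
        assert classify_error(track).call == "ambiguous"

    def test_low_coverage_excluded(self):
        track = track_from([(0, L, 3.0)], coverage=0.4)
        with pytest.raises(ValueError, match="C=0.40"):
            classify_error(track)

    def test_exhaustive_grid_against_rule_transcription(self):
        """Decision tree equals a straight-line restatement of the rules."""

        def rules(bph, sph, peri_bph, peri_sph):
            if bph >= 0.10:
                if peri_bph >= 0.50:
                    return "MI"
                if peri_sph >= 0.50:
                    return "MII"
                return "ambiguous"
            if sph >= 0.50:
                return "mitotic"
            return "ambiguous"

        grid = np.linspace(0, 1, 6)
        for bph in grid:
            for sph in grid:
                if bph + sph > 1:
                    continue
                for peri_bph in grid:
                    for peri_sph in grid:
                        if peri_bph + peri_sph > 1:
                            continue
                        # build a track realizing exactly these fractions:
                        # pericentromere is [40,60] Mbp (20% of L)
                        regions = []
                        peri_len = 20_000_000
                        b = int(peri_bph * peri_len)
                        s = int(peri_sph * peri_len)
                        if b:
                            regions.append((40_000_000, 40_000_000 + b, 3.0))
                        if s:
                            regions.append((40_000_000 + b, 40_000_000 + b + s, -3.0))
                        rest_b = int(bph * L) - b
                        rest_s = int(sph * L) - s
                        if rest_b < 0 or rest_s < 0 or rest_b + rest_s > 40_000_000:
                            continue  # not realizable distally on the left arm
                        if rest_b:
                            regions.append((0, rest_b, 3.0))
                        if rest_s:
                            regions.append((rest_b, rest_b + rest_s, -3.0))
                        track = track_from(regions or [(0, 1, 0.0)])
                        got = classify_error(track)
                        want = rules(
                            got.bph_fraction,
                            got.sph_fraction,
                            got.peri_bph_fraction,
                            got.peri_sph_fraction,
                        )
                        assert got.call == want


class TestEcdf:
    def test_single_position_step(self):
        d = CrossoverDistribution(np.array([1000.0]), 10_000)
        assert d.ecdf(999) == 0.0
        assert d.ecdf(1000) == 1.0
        assert d.ecdf(5000) == 1.0

    def test_counting(self):
        d = CrossoverDistribution(np.array([10.0, 20.0, 30.0]), 100)
        assert d.ecdf(20) == pytest.approx(2 / 3)

    def test_monotone(self):
        rng = np.random.default_rng(81)
        d = CrossoverDistribution(rng.uniform(0, 1e6, 50), 1_000_000)
        q = np.linspace(0, 1e6 - 1, 200)
        vals = d.ecdf(q)
        assert np.all(np.diff(vals) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CrossoverDistribution(np.array([]), 100)


class TestKsPermutation:
    def test_identical_samples(self):
        s = [1.0, 2.0, 3.0]
        d, p = ks_permutation(s, s, mode="exact")
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_samples_exact(self):
        d, p = ks_permutation([1, 2, 3], [7, 8, 9], mode="exact")
        assert d == 1.0
        assert p == pytest.approx(2 / 20)

    def test_d_matches_scipy(self):
        rng = np.random.default_rng(91)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 15)
        assert ks_statistic(a, b) == pytest.approx(
            stats.ks_2samp(a, b).statistic
        )

    def test_exact_and_monte_carlo_agree(self):
        rng = np.random.default_rng(92)
        a = list(rng.uniform(0, 1, 5))
        b = list(rng.uniform(0, 1, 5))
        d_e, p_e = ks_permutation(a, b, mode="exact")
        d_m, p_m = ks_permutation(
            a, b, mode="monte-carlo", n_permutations=4000, seed=7
        )
        assert d_e == d_m
        se = np.sqrt(p_e * (1 - p_e) / 4000)
        assert abs(p_m - p_e) < 3 * se + 1 / 4000

    def test_null_pvalues_valid(self):
        """Under H0 the permutation p-value is valid: P(p <= a) <= a.

        Exact permutation p-values are discrete (super-uniform), so the
        check is one-sided dominance at a grid of levels, with Monte Carlo
        slack.
        """
        rng = np.random.default_rng(93)
        n_rep = 200
        pvals = np.array(
            [
                ks_permutation(rng.uniform(0, 1, 6), rng.uniform(0, 1, 6), "exact")[1]
                for _ in range(n_rep)
            ]
        )
        for alpha in (0.05, 0.1, 0.25, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / n_rep)
            assert np.mean(pvals <= alpha) <= alpha + 3 * se

    def test_exact_limit_suggests_monte_carlo(self):
        a = list(range(12))
        b = list(range(12, 24))
        with pytest.raises(ValueError, match="monte-carlo"):
            ks_permutation(a, b, mode="exact", max_exact=100)
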