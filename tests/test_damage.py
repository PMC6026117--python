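"""Misincorporation profiling, overhang-model fitting, damage calls,
and the paired signed-rank comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats

from paleoprof import (
    AlignmentRecord,
    BriggsParams,
    SampleConfig,
    compare_paired_damage,
    damage_presence,
    fit_briggs,
    misincorporation_profile,
    perfect_alignments,
    simulate_reads,
    wilcoxon_signed_rank,
)
from paleoprof.damage import DamageProfile

from conftest import STANDARD_DAMAGE


def _profile_from_rates(rates, opportunities=10000, k=None):
    rates = np.asarray(rates, dtype=float)
    k = k or rates.size
    opp = np.full(k, opportunities, dtype=np.int64)
    hits = np.rint(rates * opportunities).astype(np.int64)
    return DamageProfile(
        k=k,
        ct5=hits / opp,
        ga3=np.full(k, np.nan),
        ct5_opportunities=opp,
        ct5_hits=hits,
        ga3_opportunities=np.zeros(k, dtype=np.int64),
        ga3_hits=np.zeros(k, dtype=np.int64),
    )


class TestMisincorporationProfile:
    def test_perfect_alignments_give_zero_rates(self):
        alns = [
            AlignmentRecord(f"r{i}", "ref", 0, "+", "CCGGAACCGGAACCGGAACCGGAACCGGAA",
                            "CCGGAACCGGAACCGGAACCGGAACCGGAA")
            for i in range(5)
        ]
        profile = misincorporation_profile(alns)
        assert np.nansum(profile.ct5) == 0.0
        assert np.nansum(profile.ga3) == 0.0

    def test_counted_fraction_at_first_position(self):
        """10 alignments with reference C at 5' position 1, 3 read as T."""
        ref = "C" + "A" * 39
        alns = [
            AlignmentRecord(f"r{i}", "ref", 0, "+",
                            ("T" if i < 3 else "C") + "A" * 39, ref)
            for i in range(10)
        ]
        profile = misincorporation_profile(alns)
        assert profile.ct5[0] == pytest.approx(0.3)
        assert profile.ct5_opportunities[0] == 10

    def test_zero_opportunity_positions_are_nan_not_zero(self):
        alns = [AlignmentRecord("r", "ref", 0, "+", "A" * 40, "A" * 40)]
        profile = misincorporation_profile(alns)
        assert np.isnan(profile.ct5).all()

    def test_short_reads_split_between_termini(self):
        """A 10 bp read with k=15 contributes its 5' half to ct5 only and
        its 3' half to ga3 only."""
        #      read:  C A A A A A A A G A
        # positions:  1 2 3 4 5 (5' half) | 6..10 (3' half)
        aln = AlignmentRecord("r", "ref", 0, "+", "CAAAAAAAGA", "CAAAAAAAGA")
        profile = misincorporation_profile([aln], k=15)
        assert profile.ct5_opportunities[0] == 1          # C at 5' position 1
        assert profile.ga3_opportunities[1] == 1          # G at 3' position 2
        assert profile.ct5_opportunities.sum() == 1
        assert profile.ga3_opportunities.sum() == 1

    def test_simulated_rates_match_closed_form(self, damaged_sample):
        """Observed terminal C->T frequencies follow
        r_i = delta_s + (delta_d - delta_s)(1-lam)^i within 3 binomial SE."""
        _, _, alignments = damaged_sample
        profile = misincorporation_profile(alignments)
        expected = STANDARD_DAMAGE.expected_rate(np.arange(1, 6))
        for i in range(5):
            n = profile.ct5_opportunities[i]
            se = np.sqrt(expected[i] * (1 - expected[i]) / n)
            assert abs(profile.ct5[i] - expected[i]) <= 3 * se
        # the complementary 3' G->A signal obeys the same law (checked at
        # the terminal position, where it is strongest)
        n3 = profile.ga3_opportunities[0]
        se3 = np.sqrt(expected[0] * (1 - expected[0]) / n3)
        assert abs(profile.ga3[0] - expected[0]) <= 3 * se3


class TestFitBriggs:
    def test_noiseless_inverse(self):
        rates = STANDARD_DAMAGE.expected_rate(np.arange(1, 16))
        profile = _profile_from_rates(rates)
        profile.ct5 = rates  # exact, not rounded to counts
        fit = fit_briggs(profile)
        assert fit.lam_identifiable
        assert fit.params.lam == pytest.approx(0.3, abs=1e-6)
        assert fit.params.delta_d == pytest.approx(0.4, abs=1e-6)
        assert fit.params.delta_s == pytest.approx(0.01, abs=1e-6)

    def test_flat_zero_profile_unidentifiable(self):
        fit = fit_briggs(_profile_from_rates(np.zeros(15)))
        assert not fit.lam_identifiable
        assert fit.params.delta_d == 0.0 and fit.params.delta_s == 0.0

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            fit_briggs(_profile_from_rates([0.2, 0.1, 0.05]))

    def test_recovery_from_simulated_sample(self, damaged_sample):
        _, _, alignments = damaged_sample
        fit = fit_briggs(misincorporation_profile(alignments))
        assert fit.params.lam == pytest.approx(0.3, abs=0.05)
        assert fit.params.delta_d == pytest.approx(0.4, abs=0.05)
        assert fit.params.delta_s == pytest.approx(0.01, abs=0.01)

    def test_pooling_ga3_uses_both_termini(self, damaged_sample):
        _, _, alignments = damaged_sample
        profile = misincorporation_profile(alignments)
        fit = fit_briggs(profile, pool_ga3=True)
        assert fit.n_positions == 30
        assert fit.params.lam == pytest.approx(0.3, abs=0.05)


class TestDamagePresence:
    def test_clear_damage_is_positive(self):
        rates = np.concatenate([[0.20], np.full(14, 0.01)])
        verdict = damage_presence(_profile_from_rates(rates, opportunities=1000))
        assert verdict.status == "positive" and verdict.is_damaged is True

    def test_flat_zero_is_negative(self):
        verdict = damage_presence(_profile_from_rates(np.zeros(15)))
        assert verdict.status == "negative" and verdict.is_damaged is False

    def test_underpowered_is_indeterminate(self):
        rates = np.concatenate([[0.02], np.full(14, 0.0)])
        verdict = damage_presence(_profile_from_rates(rates, opportunities=50))
        assert verdict.status == "indeterminate" and verdict.is_damaged is None

    def test_contaminant_only_sample_is_negative(self, genome50):
        config = SampleConfig(
            taxa=((genome50, 1.0),),
            n_reads=2000,
            damage=STANDARD_DAMAGE,
            contaminant_fraction=1.0,
            seed=21,
        )
        reads, truths = simulate_reads(config)
        alignments = perfect_alignments(reads, truths, {"genome50": genome50})
        verdict = damage_presence(misincorporation_profile(alignments))
        assert verdict.status == "negative"


def _brute_force_signed_rank(a, b):
    """Exhaustive sign-flip enumeration of the signed-rank two-sided p."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((0, 1), repeat=n)
        ]
    )
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


class TestSignedRank:
    def test_identical_vectors_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            result = compare_paired_damage([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.pvalue == 1.0

    def test_matches_enumeration_for_unit_shift_pairs(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        result = compare_paired_damage(a, b)
        assert result.method == "exact"
        assert result.pvalue == pytest.approx(_brute_force_signed_rank(a, b))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.3, 1.0, size=12)
        b = rng.normal(0.0, 1.0, size=12)
        result = wilcoxon_signed_rank(a, b)
        assert result.pvalue == pytest.approx(_brute_force_signed_rank(a, b))

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(10):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            ours = wilcoxon_signed_rank(a, b)
            theirs = stats.wilcoxon(a, b, mode="exact")
            assert ours.pvalue == pytest.approx(theirs.pvalue)

    def test_normal_approximation_close_to_exact(self, rng):
        """At n = 12 the continuity-corrected large-sample approximation
        tracks the exact enumeration to ~0.01 on average (the exact
        two-sided p is a lattice with spacing up to ~0.03, so a pathwise
        0.01 bound is unattainable for any continuous approximation)."""
        deviations = []
        for _ in range(10):
            a = rng.normal(0.4, 1.0, size=12)
            b = rng.normal(0.0, 1.0, size=12)
            exact = wilcoxon_signed_rank(a, b, exact_max_n=25)
            approx = wilcoxon_signed_rank(a, b, exact_max_n=0)
            assert approx.method == "normal"
            deviations.append(abs(exact.pvalue - approx.pvalue))
        assert np.mean(deviations) <= 0.01
        assert max(deviations) <= 0.02

    def test_large_n_uses_normal_method(self, rng):
        a = rng.normal(0.2, 1.0, size=30)
        b = rng.normal(0.0, 1.0, size=30)
        assert wilcoxon_signed_rank(a, b).method == "normal"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])
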