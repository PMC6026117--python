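"""Simulator: fragment drawing, survival, deamination, sample generation."""

import numpy as np
import pytest

from paleoprof import (
    BriggsParams,
    LengthModel,
    SampleConfig,
    SurvivalModel,
    apply_damage,
    draw_fragments,
    melting_temperature,
    perfect_alignments,
    random_genome,
    read_truth,
    simulate_reads,
    simulate_sample,
    survival_probability,
    write_truth,
)
from paleoprof.sim_reads import fragment_gc_counts

from conftest import STANDARD_DAMAGE


class TestDrawFragments:
    def test_empty(self, genome50):
        assert draw_fragments(genome50, 0, LengthModel(), 1) == []

    def test_median_matches_length_model(self, genome50):
        """Sample median of 10k lognormal draws sits at the model median."""
        frags = draw_fragments(genome50, 10000, LengthModel(location=70.0), 7)
        lengths = [end - start for start, end, _ in frags]
        assert abs(np.median(lengths) - 70.0) <= 2.0

    def test_deterministic_given_seed(self, genome50):
        a = draw_fragments(genome50, 50, LengthModel(), 9)
        b = draw_fragments(genome50, 50, LengthModel(), 9)
        assert a == b

    def test_reference_too_short_names_reference(self):
        tiny = random_genome("tiny_ref", 100, 0.5, 1)
        with pytest.raises(ValueError, match="tiny_ref"):
            draw_fragments(tiny, 5, LengthModel(max_len=250), 1)

    def test_fragments_within_reference_and_length_bounds(self, genome50):
        model = LengthModel(min_len=30, max_len=120)
        for start, end, strand in draw_fragments(genome50, 500, model, 3):
            assert 0 <= start < end <= len(genome50)
            assert 30 <= end - start <= 120
            assert strand in "+-"


class TestSurvival:
    def test_mode_none_is_unity(self):
        assert survival_probability(37, 12, SurvivalModel.none()) == 1.0

    def test_hard_threshold_semantics(self):
        model = SurvivalModel.hard_threshold(45)
        assert survival_probability(44, 10, model) == 0.0
        assert survival_probability(46, 10, model) == 1.0

    def test_logistic_monotone_in_gc(self):
        model = SurvivalModel.logistic_tm(midpoint_c=63.0, steepness=2.0)
        p_low = survival_probability(60, int(0.3 * 60), model)
        p_high = survival_probability(60, int(0.6 * 60), model)
        assert p_low <= p_high

    def test_logistic_monotone_in_length_at_fixed_gc_fraction(self):
        model = SurvivalModel.logistic_tm(midpoint_c=63.0, steepness=2.0)
        probs = [
            survival_probability(length, 0.4 * length, model)
            for length in range(30, 150, 10)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))

    def test_length_gated_always_survives_above_cutoff(self):
        model = SurvivalModel.sharp_length_cutoff(45.0, 0.30)
        assert survival_probability(45, 0, model) == 1.0
        # a 44 bp fragment at genomic GC is just below the melting cutoff
        assert survival_probability(44, int(0.30 * 44), model) < 0.5
        # but a GC-rich short fragment persists
        assert survival_probability(40, 24, model) > 0.9

    def test_gc_exceeding_length_is_an_error(self):
        with pytest.raises(ValueError):
            survival_probability(30, 31, SurvivalModel.none())

    def test_probabilities_bounded(self):
        for model in (
            SurvivalModel.none(),
            SurvivalModel.hard_threshold(45),
            SurvivalModel.logistic_tm(63.0, 5.0),
            SurvivalModel.sharp_length_cutoff(45.0, 0.3),
        ):
            for length in (20, 45, 100):
                for gc in (0, length // 2, length):
                    p = survival_probability(length, gc, model)
                    assert 0.0 <= p <= 1.0

    def test_melting_temperature_increases_with_gc(self):
        assert melting_temperature(50, 30) > melting_temperature(50, 15)


class TestApplyDamage:
    def test_zero_deltas_leave_sequence_unchanged(self):
        seq = "ACGTACGTAC"
        out, hits = apply_damage(seq, BriggsParams(0.3, 0.0, 0.0), 1)
        assert out == seq and hits == []

    def test_no_substrate(self):
        out, hits = apply_damage("AAATTT", STANDARD_DAMAGE, 1)
        assert out == "AAATTT" and hits == []

    def test_only_ct_and_ga_substitutions(self, rng):
        seq = "ACGT" * 20
        for _ in range(50):
            out, hits = apply_damage(seq, BriggsParams(0.2, 0.8, 0.1), rng)
            assert len(out) == len(seq)
            for i, (a, b) in enumerate(zip(seq, out)):
                if a != b:
                    assert (a, b) in {("C", "T"), ("G", "A")}
                    assert i in hits

    def test_terminal_rate_matches_closed_form(self, rng):
        """C->T at 5' position 1 occurs at delta_s + (delta_d-delta_s)(1-lam)."""
        n = 20000
        hits = 0
        for _ in range(n):
            out, _ = apply_damage("C" + "A" * 29, STANDARD_DAMAGE, rng)
            hits += out[0] == "T"
        expected = float(STANDARD_DAMAGE.expected_rate(1))  # 0.283
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) <= 3 * se

    def test_non_acgt_error_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            apply_damage("ACNT", STANDARD_DAMAGE, 1)

    def test_deterministic_given_seed(self):
        seq = "CCCGGGCCCGGG"
        assert apply_damage(seq, STANDARD_DAMAGE, 5) == apply_damage(
            seq, STANDARD_DAMAGE, 5
        )


class TestBriggsParams:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            BriggsParams(lam=0.0)
        with pytest.raises(ValueError):
            BriggsParams(delta_d=1.5)

    def test_inverted_deltas_warn_not_error(self):
        with pytest.warns(UserWarning):
            BriggsParams(lam=0.3, delta_d=0.01, delta_s=0.4)


class TestSimulateSample:
    def test_empty_sample(self, genome50, tmp_path):
        config = SampleConfig(taxa=((genome50, 1.0),), n_reads=0, seed=1)
        reads, truths = simulate_sample(
            config, tmp_path / "s.fastq", tmp_path / "s.tsv"
        )
        assert reads == [] and truths == []
        assert (tmp_path / "s.fastq").read_text() == ""
        assert (tmp_path / "s.tsv").read_text().startswith("read_id\t")

    def test_contaminants_bypass_damage(self, genome50):
        config = SampleConfig(
            taxa=((genome50, 1.0),),
            n_reads=500,
            damage=STANDARD_DAMAGE,
            contaminant_fraction=1.0,
            seed=2,
        )
        _, truths = simulate_reads(config)
        assert truths
        assert all(t.is_contaminant for t in truths)
        assert all(t.damaged_positions == () for t in truths)

    def test_taxon_shares_follow_abundances(self, genome30, genome50):
        config = SampleConfig(
            taxa=((genome30, 0.9), (genome50, 0.1)),
            n_reads=20000,
            damage=BriggsParams(0.3, 0.0, 0.0),
            seed=3,
        )
        _, truths = simulate_reads(config)
        share = np.mean([t.taxon_id == "genome30" for t in truths])
        se = np.sqrt(0.9 * 0.1 / len(truths))
        assert abs(share - 0.9) <= 3 * se

    def test_byte_identical_given_seed(self, genome50, tmp_path):
        config = SampleConfig(
            taxa=((genome50, 1.0),), n_reads=300, damage=STANDARD_DAMAGE, seed=11
        )
        for tag in ("a", "b"):
            simulate_sample(
                config, tmp_path / f"{tag}.fastq", tmp_path / f"{tag}.tsv"
            )
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_truth_roundtrip(self, damaged_sample, tmp_path):
        _, truths, _ = damaged_sample
        write_truth(truths, tmp_path / "truth.tsv")
        assert read_truth(tmp_path / "truth.tsv") == truths

    def test_conservation_and_damage_closure(self, damaged_sample):
        """Reads and truth rows correspond one-to-one, and every mismatch
        against the true reference interval is a recorded C->T or G->A."""
        reads, truths, alignments = damaged_sample
        assert len(reads) == len(truths) == len(alignments)
        assert {r.read_id for r in reads} == {t.read_id for t in truths}
        for aln, truth in zip(alignments, truths):
            assert sorted(p for p, _, _ in aln.mismatches) == sorted(
                truth.damaged_positions
            )
            for _, ref, read in aln.mismatches:
                assert (ref, read) in {("C", "T"), ("G", "A")}

    def test_survival_thinning_enriches_gc_of_short_fragments(self, genome30):
        """Under melting-temperature survival, surviving short fragments are
        GC-enriched relative to the genome."""
        midpoint = float(melting_temperature(55, 0.3 * 55))
        config = SampleConfig(
            taxa=((genome30, 1.0),),
            n_reads=15000,
            damage=BriggsParams(0.3, 0.0, 0.0),
            survival=SurvivalModel.logistic_tm(midpoint, steepness=2.0),
            seed=4,
        )
        reads, truths = simulate_reads(config)
        assert len(reads) >= 10000 * 0.5  # thinning happened but sample is large
        assert len(reads) < 15000
        short_gc = [r.gc_fraction for r in reads if r.length < 55]
        assert len(short_gc) > 200
        assert np.mean(short_gc) > genome30.genomic_gc

    def test_abundances_must_sum_to_one(self, genome50):
        with pytest.raises(ValueError):
            SampleConfig(taxa=((genome50, 0.5),), n_reads=10, seed=1)

    def test_empty_taxa_list_rejected(self):
        with pytest.raises(ValueError):
            SampleConfig(taxa=(), n_reads=10, seed=1)


def test_fragment_gc_counts_match_slices(genome50):
    frags = draw_fragments(genome50, 200, LengthModel(), 5)
    counts = fragment_gc_counts(genome50, frags)
    for (start, end, _), count in zip(frags, counts):
        sub = genome50.sequence[start:end]
        assert count == sub.count("G") + sub.count("C")
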