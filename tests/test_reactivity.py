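"""Mutation counting, background correction, box normalization, profile I/O."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from shapesort import mapsim, reactivity
from shapesort.mapsim import GroundTruthProfile, SimulationConfig
from shapesort.reactivity import (
    MutationCounts,
    ReactivityProfile,
    box_multiplier,
    count_mutations,
    make_profile_from_counts,
    normalize_profile,
    raw_reactivity,
    read_profile,
    write_profile,
)

from conftest import make_header, make_read


def brute_force_box_multiplier(values):
    """Independent restatement of the 2%/8% rule: drop the top 2% of the
    sorted values, average the next 8%, invert."""
    v = sorted((x for x in values if not np.isnan(x)), reverse=True)
    n = len(v)
    n_excl = max(1, int(n * 0.02))
    n_band = max(1, int(n * 0.08))
    band = v[n_excl : n_excl + n_band]
    return 1.0 / (sum(band) / len(band))


class TestCountMutations:
    def test_events_and_depth(self):
        hdr = make_header(length=10)
        ref = "ACGTACGTAC"
        reads = [make_read(hdr, f"r{i}", start=0, seq=ref) for i in range(3)]
        reads.append(make_read(hdr, "m", start=0, seq="AGGTACGTAC"))
        counts = count_mutations(reads, ref)
        assert counts.effective_depth[1] == 4
        assert counts.mutation_events[1] == 1
        assert counts.mutation_events[0] == 0

    def test_uncovered_position_zero(self):
        hdr = make_header(length=10)
        reads = [make_read(hdr, "r", start=0, seq="ACGT")]
        counts = count_mutations(reads, "ACGTACGTAC")
        assert counts.effective_depth[8] == 0 and counts.mutation_events[8] == 0

    def test_quality_filter_reduces_depth(self):
        hdr = make_header(length=10)
        reads = [make_read(hdr, "r", start=0, seq="ACGT", qual=5)]
        counts = count_mutations(reads, "ACGTACGTAC", min_base_quality=20)
        assert counts.effective_depth.sum() == 0

    def test_order_independent(self, hairpin_profile, rng):
        cfg = SimulationConfig(depth=300, read_length=30, seed=41)
        reads, _ = mapsim.simulate_reads(hairpin_profile, None, cfg, "treated")
        ref = hairpin_profile.dna_sequence
        a = count_mutations(reads, ref)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        b = count_mutations(shuffled, ref)
        np.testing.assert_array_equal(a.mutation_events, b.mutation_events)
        np.testing.assert_array_equal(a.effective_depth, b.effective_depth)

    def test_rates_match_binomial_oracle(self, hairpin_profile):
        cfg = SimulationConfig(
            depth=20000, read_length=60, paired_end=False,
            background_rate=0.002, mod_detection_scale=0.03, seed=42,
        )
        reads, _ = mapsim.simulate_reads(hairpin_profile, None, cfg, "treated")
        counts = count_mutations(reads, hairpin_profile.dna_sequence)
        p = np.clip(0.002 + 0.03 * hairpin_profile.reactivity, 0, 1)
        se = np.sqrt(p * (1 - p) / counts.effective_depth)
        within = np.abs(counts.rate - p) <= 3 * se
        assert within.mean() >= 0.95

    def test_invariant_events_bounded_by_depth(self):
        with pytest.raises(ValueError):
            MutationCounts(np.array([5]), np.array([3]))


class TestRawReactivity:
    def test_background_subtraction(self):
        t = MutationCounts(np.array([50]), np.array([1000]), "treated")
        u = MutationCounts(np.array([10]), np.array([1000]), "untreated")
        assert raw_reactivity(t, u, min_depth=100)[0] == pytest.approx(0.04)

    def test_negative_values_retained(self):
        t = MutationCounts(np.array([10]), np.array([1000]), "treated")
        u = MutationCounts(np.array([20]), np.array([1000]), "untreated")
        assert raw_reactivity(t, u, min_depth=100)[0] == pytest.approx(-0.01)

    def test_low_depth_missing(self):
        t = MutationCounts(np.array([10]), np.array([500]), "treated")
        u = MutationCounts(np.array([10]), np.array([2000]), "untreated")
        assert np.isnan(raw_reactivity(t, u, min_depth=1000)[0])

    def test_length_mismatch_rejected(self):
        t = MutationCounts(np.zeros(5, int), np.ones(5, int))
        u = MutationCounts(np.zeros(4, int), np.ones(4, int))
        with pytest.raises(ValueError):
            raw_reactivity(t, u)


class TestNormalization:
    def _profile(self, values):
        n = len(values)
        return ReactivityProfile(
            sequence="A" * n,
            raw_rate_treated=np.zeros(n),
            raw_rate_untreated=np.zeros(n),
            depth_treated=np.full(n, 2000),
            depth_untreated=np.full(n, 2000),
            raw_reactivity=np.asarray(values, dtype=float),
        )

    def test_constant_profile_multiplier(self):
        prof = normalize_profile(self._profile([2.0] * 100))
        assert prof.normalization_multiplier == pytest.approx(0.5)
        assert np.allclose(prof.normalized_reactivity, 1.0)

    def test_matches_brute_force_oracle(self):
        values = np.random.default_rng(50).gamma(1.0, 1.0, size=50)
        assert box_multiplier(values) == pytest.approx(
            brute_force_box_multiplier(values), abs=1e-12
        )

    def test_external_reference_self_identity(self):
        values = np.random.default_rng(51).gamma(1.0, 1.0, size=80)
        a = normalize_profile(self._profile(values), "box2_8")
        b = normalize_profile(
            self._profile(values), "external_reference", reference_profile=values
        )
        assert a.normalization_multiplier == pytest.approx(b.normalization_multiplier)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(52)
        values = rng.gamma(1.0, 1.0, size=120)
        base = box_multiplier(values)
        for _ in range(20):
            c = rng.uniform(0.1, 10)
            assert box_multiplier(c * values) == pytest.approx(base / c, rel=1e-9)

    def test_too_few_positions_refused(self):
        with pytest.raises(ValueError, match="20"):
            box_multiplier(np.ones(10))

    def test_missing_positions_stay_missing(self):
        values = np.random.default_rng(53).gamma(1.0, 1.0, size=60)
        values[7] = np.nan
        prof = normalize_profile(self._profile(values))
        assert np.isnan(prof.normalized_reactivity[7])


class TestProfileIO:
    def _toy_profile(self):
        rng = np.random.default_rng(60)
        n = 30
        raw = rng.gamma(1.0, 1.0, size=n)
        raw[4] = np.nan
        return ReactivityProfile(
            sequence="ACGU" * 7 + "AC",
            raw_rate_treated=rng.random(n) * 0.05,
            raw_rate_untreated=rng.random(n) * 0.01,
            depth_treated=np.full(n, 1500),
            depth_untreated=np.full(n, 1500),
            raw_reactivity=raw,
        )

    def test_round_trip(self, tmp_path):
        prof = self._toy_profile()
        path = tmp_path / "p.map"
        write_profile(prof, path)
        back = read_profile(path)
        assert back.sequence == prof.sequence
        np.testing.assert_allclose(
            back.reactivity, prof.reactivity, atol=1e-6, equal_nan=True
        )

    def test_missing_encoded_as_sentinel(self, tmp_path):
        prof = self._toy_profile()
        path = tmp_path / "p.map"
        write_profile(prof, path)
        line5 = path.read_text().splitlines()[4]
        assert line5.split("\t")[1] == "-999.000000"
        assert np.isnan(read_profile(path).reactivity[4])

    def test_empty_profile_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_profile_path = tmp_path / "empty.map"
            read_profile_path.write_text("")
            read_profile(read_profile_path)

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.map"
        path.write_text("1\t0.5\t0\tA\nnot-a-number\tx\t0\tC\n")
        with pytest.raises(ValueError, match="line 2"):
            read_profile(path)


def test_end_to_end_estimator_recovery():
    """Simulated reads at high depth recover the ground-truth reactivity
    profile (Pearson r > 0.9 over a 200-nt transcript)."""
    rng = np.random.default_rng(70)
    seq = mapsim.random_sequence(200, seed=70)
    react = np.where(rng.random(200) < 0.5, rng.gamma(0.6, 0.1, 200),
                     rng.gamma(2.0, 0.6, 200))
    profile = GroundTruthProfile(seq, react, np.zeros(200, bool))
    cfg = SimulationConfig(
        depth=5000, read_length=50, fragment_length_mean=80,
        fragment_length_sd=20, background_rate=0.002,
        mod_detection_scale=0.03, seed=71,
    )
    channels = {}
    for ch in ("treated", "untreated"):
        reads, _ = mapsim.simulate_reads(profile, None, cfg, ch)
        channels[ch] = count_mutations(reads, seq)
    prof = make_profile_from_counts(seq, channels["treated"], channels["untreated"])
    ok = ~np.isnan(prof.raw_reactivity)
    assert ok.sum() > 100
    r = pearsonr(prof.raw_reactivity[ok], react[ok]).statistic
    assert r > 0.9
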