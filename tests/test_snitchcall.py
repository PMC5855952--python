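"""Profile comparison features, classification, splits, ROC, design evaluation."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, pearsonr, spearmanr

from shapesort import mapsim, snitchcall
from shapesort.mapsim import SimulationConfig
from shapesort.snitchcall import (
    ComparisonFeatures,
    ThresholdModel,
    classify,
    compare_profiles,
    evaluate_designs,
    load_model,
    ratiometric_split,
    roc_auc,
    save_model,
    simulate_comparison,
    train_on_synthetic,
)

from conftest import make_header, make_read


class TestCompareProfiles:
    def test_identical_profiles(self, rng):
        v = rng.gamma(1.0, 1.0, size=101)
        f = compare_profiles(v, v.copy(), 50)
        assert f.pearson_r == pytest.approx(1.0)
        assert f.esdc == pytest.approx(0.0, abs=1e-9)
        assert f.n_changed == 0 and f.max_abs_delta == 0.0

    def test_negated_centered_profile(self, rng):
        v = rng.normal(0.0, 1.0, size=101)
        v -= v.mean()
        f = compare_profiles(v, -v, 50)
        assert f.pearson_r == pytest.approx(-1.0)
        assert f.esdc == pytest.approx(2 * np.sqrt(f.n_compared))

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(80)
        a = rng.gamma(1.0, 1.0, size=100)
        b = a + rng.normal(0, 0.4, size=100)
        pos, w = 50, 30
        f = compare_profiles(a, b, pos, window_halfwidth=w, change_threshold=0.5)
        idx = np.array([i for i in range(pos - w, pos + w + 1) if i != pos])
        x, y = a[idx], b[idx]
        assert f.n_compared == len(idx)
        assert f.pearson_r == pytest.approx(pearsonr(x, y).statistic)
        assert f.spearman_rho == pytest.approx(spearmanr(x, y).statistic)
        assert f.esdc == pytest.approx((1 - pearsonr(x, y).statistic) * np.sqrt(len(idx)))
        assert f.max_abs_delta == pytest.approx(np.max(np.abs(y - x)))
        assert f.n_changed == int((np.abs(y - x) >= 0.5).sum())
        assert f.signed_area_before == pytest.approx((y - x)[idx < pos].sum())
        assert f.signed_area_after == pytest.approx((y - x)[idx > pos].sum())

    def test_variant_position_excluded(self, rng):
        v = rng.gamma(1.0, 1.0, size=101)
        w = v.copy()
        w[50] += 100.0  # only the variant site differs
        f = compare_profiles(v, w, 50)
        assert f.max_abs_delta == 0.0

    def test_esdc_scale_law(self, rng):
        """eSDC quadruples the window, doubles the statistic at fixed r."""
        x = rng.normal(0, 1, size=25)
        y = x + rng.normal(0, 0.5, size=25)
        f1 = compare_profiles(x, y, len(x), window_halfwidth=1000)
        f4 = compare_profiles(np.tile(x, 4), np.tile(y, 4), 100, window_halfwidth=1000)
        assert f4.pearson_r == pytest.approx(f1.pearson_r)
        assert f4.esdc == pytest.approx(2 * f1.esdc)

    def test_insufficient_overlap_rejected(self):
        v = np.full(101, np.nan)
        v[48:53] = 1.0
        with pytest.raises(ValueError, match="insufficient overlap"):
            compare_profiles(v, v, 50)


class TestClassify:
    def test_identical_profiles_are_nonchanger_under_any_model(self, rng):
        v = rng.gamma(1.0, 1.0, size=101)
        f = compare_profiles(v, v.copy(), 50)
        for model in (ThresholdModel(), ThresholdModel(threshold=0.0)):
            assert classify(f, model).label == "nonchanger"

    def test_planted_block_called_ribosnitch(self):
        rng = np.random.default_rng(81)
        f = simulate_comparison(rng, effect=2.0, noise_sd=0.05)
        call = classify(f, ThresholdModel())
        assert call.label == "riboSNitch"
        assert call.score >= ThresholdModel().threshold

    def test_replicate_noise_null_mostly_nonchanger(self):
        rng = np.random.default_rng(82)
        model = ThresholdModel()
        labels = [
            classify(simulate_comparison(rng, effect=0.0, noise_sd=0.1), model).label
            for _ in range(100)
        ]
        assert labels.count("nonchanger") >= 90

    def test_missing_model_rejected(self, rng):
        v = rng.gamma(1.0, 1.0, size=101)
        with pytest.raises(ValueError):
            classify(compare_profiles(v, v, 50), None)


class TestTrainOnSynthetic:
    def test_zero_effect_grid_refused(self):
        with pytest.raises(ValueError, match="degenerate"):
            train_on_synthetic(50, 50, effect_grid=(0.0,), seed=1)

    def test_too_few_examples_refused(self):
        with pytest.raises(ValueError, match="50"):
            train_on_synthetic(10, 200, seed=1)

    def test_same_seed_identical_serialized_model(self, tmp_path):
        for name in ("a.pkl", "b.pkl"):
            train_on_synthetic(50, 50, seed=5, path=tmp_path / name)
        assert (tmp_path / "a.pkl").read_bytes() == (tmp_path / "b.pkl").read_bytes()

    def test_round_trip_and_scoring(self, tmp_path):
        model = train_on_synthetic(50, 50, seed=6, path=tmp_path / "m.pkl")
        back = load_model(tmp_path / "m.pkl")
        rng = np.random.default_rng(7)
        f = simulate_comparison(rng, effect=2.0, noise_sd=0.05)
        assert back.score(f) == pytest.approx(model.score(f))
        assert back.score(f) > 0.5


class TestRatiometricSplit:
    def _pairs(self, n):
        hdr = make_header(length=100)
        reads = []
        for i in range(n):
            reads.append(make_read(hdr, f"p{i}", start=0, seq="ACGT", flag=99))
            reads.append(make_read(hdr, f"p{i}", start=10, seq="ACGT", flag=147))
        return reads

    def test_exact_split_sizes(self):
        a, b = ratiometric_split(self._pairs(1000), (0.75, 0.25), seed=1)
        assert len({r.query_name for r in a}) == 750
        assert len({r.query_name for r in b}) == 250

    def test_largest_remainder_rounding(self):
        a, b = ratiometric_split(self._pairs(999), (0.75, 0.25), seed=1)
        assert len({r.query_name for r in a}) == 749
        assert len({r.query_name for r in b}) == 250

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            ratiometric_split(self._pairs(100), (1.0, 0.0), seed=1)

    def test_disjoint_union_at_pair_level(self):
        reads = self._pairs(40)
        a, b = ratiometric_split(reads, (0.75, 0.25), seed=2)
        ids_a = {r.query_name for r in a}
        ids_b = {r.query_name for r in b}
        assert not ids_a & ids_b
        assert ids_a | ids_b == {r.query_name for r in reads}
        # mates travel together
        assert len(a) == 2 * len(ids_a) and len(b) == 2 * len(ids_b)

    def test_split_preserves_mutation_rate_expectation(self, hairpin_profile):
        from shapesort.reactivity import count_mutations

        cfg = SimulationConfig(depth=4000, read_length=60, paired_end=False,
                               background_rate=0.01, mod_detection_scale=0.0,
                               seed=83)
        reads, _ = mapsim.simulate_reads(hairpin_profile, None, cfg, "untreated")
        ref = hairpin_profile.dna_sequence
        full = count_mutations(reads, ref)
        sub, _ = ratiometric_split(reads, (0.75, 0.25), seed=84)
        part = count_mutations(sub, ref)
        se = np.sqrt(full.rate * (1 - full.rate) / part.effective_depth)
        assert (np.abs(part.rate - full.rate) <= 4 * se + 1e-12).all()


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(85)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            )
            assert auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_equals_mann_whitney_u(self):
        rng = np.random.default_rng(86)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()))


class TestEvaluateDesigns:
    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError):
            evaluate_designs(1.0, 0.1, 2, 1000)

    def test_noise_free_high_depth_separates_perfectly(self):
        res = evaluate_designs(2.0, 0.0, 20, 50000, seed=1)
        assert res["within_sample"]["auc"] == 1.0
        assert res["between_replicate"]["auc"] == 1.0

    def test_within_sample_design_dominates_with_replicate_noise(self):
        """Allele sorting removes between-tube noise from the comparison, so
        its AUC is at least the between-replicate AUC on average."""
        gaps = []
        for seed in range(5):
            res = evaluate_designs(1.0, 0.3, 40, 2000, seed=seed)
            gaps.append(res["within_sample"]["auc"] - res["between_replicate"]["auc"])
        assert np.mean(gaps) >= 0.0

    def test_null_scores_give_chance_auc(self):
        rng = np.random.default_rng(87)
        scores = rng.random(2000)
        labels = np.tile([0, 1], 1000)
        _, auc = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.03


def test_model_files_reject_unknown_format(tmp_path):
    import pickle

    path = tmp_path / "bad.pkl"
    with open(path, "wb") as fh:
        pickle.dump({"format": 99}, fh)
    with pytest.raises(ValueError):
        load_model(path)
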