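import numpy as np
import pandas as pd
import pytest

from pbapflow.fluorescence import (
    ABC_CLASSES,
    ThresholdSet,
    apply_quality_mask,
    class_fractions,
    classify_particle,
    classify_particles,
    compute_ft_stats,
    compute_rb2a,
)
from pbapflow.synthetic_data import generate_campaign, generate_ft_records, get_preset


def _records(a, b=None, c=None):
    a = np.asarray(a, dtype=float)
    return pd.DataFrame(
        {"fl_a": a, "fl_b": a if b is None else b, "fl_c": a if c is None else c}
    )


class TestFtStats:
    def test_zero_variance_channel(self):
        th = compute_ft_stats(_records([100.0, 100.0, 100.0]))
        assert th.ft_mean[0] == 100.0 and th.ft_sd[0] == 0.0
        assert th.t3[0] == th.t9[0] == 100.0

    def test_threshold_arithmetic(self):
        # two-point sample with mean 100 and sample SD exactly 10
        d = 10.0 * np.sqrt(2.0) / 2.0
        th = compute_ft_stats(_records([100 - d, 100 + d]))
        assert th.t3 == pytest.approx([130.0] * 3)
        assert th.t9 == pytest.approx([190.0] * 3)

    def test_recovers_generator_statistics(self):
        ft = generate_ft_records(10_000, (50, 40, 30), (5, 4, 3), seed=1)
        th = compute_ft_stats(ft)
        se_mean = np.array([5, 4, 3]) / np.sqrt(10_000)
        assert np.all(np.abs(th.ft_mean - [50, 40, 30]) < 3 * se_mean)
        se_sd = np.array([5, 4, 3]) / np.sqrt(2 * 10_000)
        assert np.all(np.abs(th.ft_sd - [5, 4, 3]) < 3.5 * se_sd)

    def test_too_few_records_is_an_error(self):
        with pytest.raises(ValueError, match="channel A"):
            compute_ft_stats(_records([100.0]))

    def test_missing_channel_column(self):
        with pytest.raises(ValueError, match="fl_c"):
            compute_ft_stats(pd.DataFrame({"fl_a": [1.0, 2.0], "fl_b": [1.0, 2.0]}))


class TestClassification:
    def test_truth_table_all_patterns(self, thresholds):
        # enumerate the 8 on/off patterns: exactly 7 classes + 'none'
        t3 = thresholds.t3
        rows = []
        for code in range(8):
            rows.append(
                {f"fl_{ch}": (t3[i] + 1.0 if (code >> i) & 1 else 0.0)
                 for i, ch in enumerate("abc")}
            )
        lab = classify_particles(pd.DataFrame(rows), thresholds, 3)
        assert list(lab["abc_class"]) == list(ABC_CLASSES)
        assert set(lab.loc[lab["in_tier"], "abc_class"]) == {"A", "B", "AB", "C", "AC", "BC", "ABC"}
        assert not lab["in_tier"].iloc[0]

    def test_ac_example_and_off_tier(self, thresholds, toy_particles):
        lab = classify_particles(toy_particles, thresholds, 3)
        # particle 3 lights channels A and C only at 9 sigma
        lab9 = classify_particles(toy_particles, thresholds, 9)
        assert lab9["abc_class"].iloc[3] == "ABC"
        assert lab["abc_class"].iloc[0] == "none" and not lab["in_tier"].iloc[0]
        assert lab["abc_class"].iloc[4] == "AB"

    def test_exceedance_is_strict(self, thresholds):
        p = _records([thresholds.t3[0]], [0.0], [0.0])
        assert not classify_particles(p, thresholds, 3)["in_tier"].iloc[0]

    def test_single_record_wrapper(self, thresholds):
        lab = classify_particle(
            {"fl_a": thresholds.t3[0] + 1, "fl_b": 0.0, "fl_c": thresholds.t3[2] + 1},
            thresholds, 3,
        )
        assert lab.tier == "fluorescent" and lab.abc_class == "AC"

    def test_hyper_tier_is_subset_of_fluorescent(self, small_campaign):
        th = compute_ft_stats(small_campaign.ft_records)
        lab3 = classify_particles(small_campaign.particles, th, 3)
        lab9 = classify_particles(small_campaign.particles, th, 9)
        assert not (lab9["in_tier"] & ~lab3["in_tier"]).any()

    def test_monotonicity_over_random_streams(self, thresholds):
        # 9-sigma counts never exceed 3-sigma counts, per channel and overall
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(5, 200)
            p = _records(
                rng.lognormal(4.0, 1.0, n), rng.lognormal(4.0, 1.0, n), rng.lognormal(4.0, 1.0, n)
            )
            lab3 = classify_particles(p, thresholds, 3)
            lab9 = classify_particles(p, thresholds, 9)
            assert lab9["in_tier"].sum() <= lab3["in_tier"].sum()
            for i, ch in enumerate("abc"):
                on3 = (p[f"fl_{ch}"] > thresholds.t3[i]).sum()
                on9 = (p[f"fl_{ch}"] > thresholds.t9[i]).sum()
                assert on9 <= on3

    def test_raising_a_threshold_never_increases_on_count(self):
        rng = np.random.default_rng(5)
        amps = rng.lognormal(4.0, 1.0, 500)
        counts = [(amps > t).sum() for t in np.linspace(10, 200, 25)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRb2a:
    def test_equal_amplitudes_above_threshold(self, thresholds):
        p = _records([100.0], [100.0], [0.0])
        assert compute_rb2a(p, thresholds, 3)[0] == pytest.approx(1.0)

    def test_censoring_of_sub_threshold_channel_a(self, thresholds):
        # channel A below 3 sigma is replaced by its FT mean
        p = _records([10.0], [80.0], [0.0])
        expected = 80.0 / thresholds.ft_mean[0]
        assert compute_rb2a(p, thresholds, 3)[0] == pytest.approx(expected)

    def test_fully_censored_floor(self, thresholds):
        p = _records([10.0], [10.0], [0.0])
        expected = thresholds.ft_mean[1] / thresholds.ft_mean[0]
        assert compute_rb2a(p, thresholds, 3)[0] == pytest.approx(expected)

    def test_scale_invariance(self, thresholds):
        # rescaling amplitudes and FT statistics together leaves R_B2A unchanged
        rng = np.random.default_rng(7)
        p = _records(rng.lognormal(4, 1, 50), rng.lognormal(4, 1, 50), rng.lognormal(4, 1, 50))
        r1 = compute_rb2a(p, thresholds, 3)
        s = 3.7
        scaled = ThresholdSet(ft_mean=thresholds.ft_mean * s, ft_sd=thresholds.ft_sd * s)
        p2 = p * s
        r2 = compute_rb2a(p2, scaled, 3)
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_zero_ft_mean_a_is_an_error(self):
        th = ThresholdSet(ft_mean=np.array([0.0, 40.0, 30.0]), ft_sd=np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="FT mean"):
            compute_rb2a(_records([1.0]), th, 3)


class TestClassFractions:
    def test_single_class_stream(self, thresholds):
        p = _records([0.0] * 10, [60.0] * 10, [0.0] * 10)  # all class B at 3 sigma
        frac = class_fractions(classify_particles(p, thresholds, 3))
        assert frac["B"] == 1.0 and frac.drop("B").sum() == 0.0

    def test_fractions_sum_to_one(self, small_campaign):
        th = compute_ft_stats(small_campaign.ft_records)
        frac = class_fractions(classify_particles(small_campaign.particles, th, 3))
        assert frac.sum() == pytest.approx(1.0)

    def test_empty_tier_is_an_error(self, thresholds):
        p = _records([0.0], [0.0], [0.0])
        with pytest.raises(ValueError, match="no particles in tier"):
            class_fractions(classify_particles(p, thresholds, 3))

    def test_known_mixture_recovery(self, thresholds):
        # 60% class A, 40% class BC at 3 sigma with n = 50,000
        rng = np.random.default_rng(11)
        n = 50_000
        is_a = rng.random(n) < 0.6
        p = _records(
            np.where(is_a, 70.0, 0.0), np.where(is_a, 0.0, 60.0), np.where(is_a, 0.0, 45.0)
        )
        frac = class_fractions(classify_particles(p, thresholds, 3))
        tol = 3 * np.sqrt(0.6 * 0.4 / n)
        assert abs(frac["A"] - 0.6) < tol
        assert abs(frac["BC"] - 0.4) < tol


class TestQualityMask:
    def test_pass_all(self, toy_particles):
        kept, report = apply_quality_mask(toy_particles, "pass_all")
        assert len(kept) == len(toy_particles)
        assert report["removed_fraction"] == 0.0

    def test_unknown_mask_name(self, toy_particles):
        with pytest.raises(KeyError, match="unknown quality mask"):
            apply_quality_mask(toy_particles, "no_such_mask")

    def test_flag_mask_recovers_injected_contamination(self):
        # a third of the campaign time is flagged as exhaust-contaminated
        camp = generate_campaign(
            get_preset("pristine", duration_h=12.0, contaminated_time_fraction=0.33, seed=5)
        )
        kept, report = apply_quality_mask(camp.particles, "flagged")
        assert report["removed_fraction"] == pytest.approx(0.33, abs=0.07)
        assert (kept["quality_flags"] == 0).all()
        assert report["n_removed"] + len(kept) == report["n_input"]
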