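"""Feature extraction: worked examples, brute-force agreement, invariants."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_random_meal
from mealmetry import features as ft
from mealmetry.synth import Food, MealRecord, SensorSignal


def simple_meal(bite_times, seqs=(), swallows=(), masses=None):
    masses = masses or [10.0] * len(bite_times)
    return MealRecord(
        "S01", "M1",
        bites=[(t, m, "biscuit") for t, m in zip(bite_times, masses)],
        chew_sequences=list(seqs),
        swallows=list(swallows),
        foods=[Food("biscuit", 4.5)],
    )


class TestRegistry:
    def test_partition_sizes_sum_to_57(self):
        sizes = {name: len(group) for name, group in ft.FEATURE_GROUPS.items()}
        assert sizes == {"bite": 6, "chew": 15, "swallow": 9, "pause": 4,
                         "sensor": 23}
        assert len(ft.FEATURE_REGISTRY) == 57
        assert len(set(ft.FEATURE_REGISTRY)) == 57

    def test_family_pools_match_registry_partition(self):
        assert ft.FAMILY_POOLS["full"] == ft.FEATURE_REGISTRY
        assert len(ft.FAMILY_POOLS["bite"]) == 6
        assert len(ft.FAMILY_POOLS["sensor"]) == 23


class TestInstantaneousFrequencies:
    def test_uniform_spacing(self):
        np.testing.assert_allclose(
            ft.instantaneous_frequencies([0, 10, 20]), [0.1, 0.1])
        np.testing.assert_allclose(ft.instantaneous_frequencies([0, 2]), [0.5])

    def test_duplicate_timestamp_raises(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ft.instantaneous_frequencies([0.0, 1.0, 1.0])

    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=50, unique=True))
    @settings(deadline=None)
    def test_matches_loop_oracle(self, times):
        times = sorted(times)
        assume(all(b - a > 1e-6 for a, b in zip(times, times[1:])))
        got = ft.instantaneous_frequencies(times)
        np.testing.assert_allclose(got, oracles.inst_freqs(times), rtol=1e-12)


class TestBiteFeatures:
    def test_rates_use_eating_and_meal_denominators(self):
        meal = simple_meal(np.linspace(0, 399, 20))
        dur = ft.DurationTriple(400.0, 300.0, 0.0)
        vals = ft.bite_features(meal, dur)
        assert vals["total_bite"] == 20
        assert vals["avg_biteRate_Teating"] == pytest.approx(20 / 300)
        assert vals["avg_biteRate_Tmeal"] == pytest.approx(0.05)

    def test_single_bite_imputes_ibf_stats(self):
        meal = simple_meal([0.0], swallows=[5.0])
        vals = ft.bite_features(meal, ft.DurationTriple(5.0, 5.0, 0.0))
        assert vals["total_bite"] == 1
        assert vals["avg_IBF"] == vals["sd_IBF"] == vals["var_IBF"] == 0.0

    def test_evenly_spaced_bites_have_zero_ibf_spread(self):
        meal = simple_meal(np.arange(0, 100, 10.0))
        vals = ft.bite_features(meal, ft.DurationTriple(90.0, 90.0, 0.0))
        assert vals["sd_IBF"] == 0.0
        assert vals["var_IBF"] == 0.0


class TestChewFeatures:
    def test_constant_sequences(self):
        meal = simple_meal([i * 30.0 for i in range(10)],
                           seqs=[(i * 30 + 0.3, i * 30 + 8.3, 12)
                                 for i in range(10)])
        dur, _ = ft.durations(meal)
        vals = ft.chew_features(meal, dur)
        assert vals["total_chews"] == 120
        assert vals["total_chews_du"] == pytest.approx(80.0)
        assert vals["chewRate_Tchewing"] == pytest.approx(1.5)
        assert vals["sd_chews_perSeq"] == 0.0

    def test_equal_rates_have_zero_rate_variance(self):
        meal = simple_meal([0.0, 20.0],
                           seqs=[(0.3, 5.3, 10), (20.3, 30.3, 20)])
        dur, _ = ft.durations(meal)
        vals = ft.chew_features(meal, dur)
        assert vals["avg_chewRate_perSeq"] == pytest.approx(2.0)
        assert vals["var_chewRate_perSeq"] == pytest.approx(0.0)

    def test_zero_duration_sequence_raises(self):
        meal = simple_meal([0.0])
        meal.chew_sequences = [(0.3, 0.3 + 0, 5)]  # bypass validate
        with pytest.raises(ValueError):
            ft.chew_features(meal, ft.DurationTriple(10.0, 10.0, 0.0))


class TestSwallowFeatures:
    def test_two_swallows_per_bite(self):
        bites = [i * 30.0 for i in range(10)]
        sw = []
        for t in bites:
            sw += [t + 5.0, t + 6.0]
        meal = simple_meal(bites, swallows=sw)
        dur, _ = ft.durations(meal)
        vals = ft.swallow_features(meal, dur)
        assert vals["avg_swl_bite"] == 2.0
        assert vals["sd_swl_bite"] == 0.0

    def test_uniform_swallows_isf(self):
        meal = simple_meal([0.0], swallows=[0.5, 4.5, 8.5])
        dur, _ = ft.durations(meal)
        vals = ft.swallow_features(meal, dur)
        assert vals["avg_ISF"] == pytest.approx(0.25)


class TestPauseFeatures:
    def test_explicit_gaps(self):
        # bouts end at last swallow; gaps of 5 s and 15 s before next bites
        meal = simple_meal(
            [0.0, 15.0, 40.0],
            swallows=[10.0, 25.0, 50.0],
        )
        vals = ft.pause_features(meal)
        assert vals["total_pause_du"] == pytest.approx(20.0)
        assert vals["avg_pause_du"] == pytest.approx(10.0)

    def test_single_bout_has_zero_pause_features(self):
        meal = simple_meal([0.0], swallows=[8.0])
        vals = ft.pause_features(meal)
        assert all(v == 0.0 for v in vals.values())

    def test_pause_plus_eating_equals_meal_duration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            meal = make_random_meal(rng, with_sensor=False)
            dur, _ = ft.durations(meal)
            total_pause = ft.pause_features(meal)["total_pause_du"]
            assert total_pause + dur.eating_du_s == pytest.approx(
                dur.meal_du_s, abs=1e-9)


class TestSensorBoutFeatures:
    def test_waveform_length_of_alternating_bout(self):
        vals = ft.sensor_bout_features([0.0, 1.0, 0.0, 1.0], fs_hz=10.0)
        assert vals["Waveform_Length"] == 3.0

    def test_constant_bout(self):
        vals = ft.sensor_bout_features([2.0] * 8, fs_hz=10.0)
        assert vals["pwr"] == pytest.approx(4.0)
        assert vals["zero_crossings"] == 0.0
        assert vals["Waveform_Length"] == 0.0
        assert vals["Total_Entropy"] == 0.0

    def test_zero_power_bout_hits_db_floor(self):
        vals = ft.sensor_bout_features([0.0] * 8, fs_hz=10.0)
        assert vals["pwr_dB"] == -120.0

    def test_sinusoid_max_freq_within_one_bin(self):
        fs, dur = 100.0, 8.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 1.5 * t)
        vals = ft.sensor_bout_features(x, fs)
        assert vals["max_freq"] == pytest.approx(1.5, abs=fs / len(x))
        assert vals["autocorr_period"] == pytest.approx(1 / 1.5, abs=1 / fs)

    def test_parseval_spectral_energy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 64)
        vals = ft.sensor_bout_features(x, 16.0)
        assert vals["Spectral_energy"] == pytest.approx(np.sum(x**2), rel=1e-9)

    def test_too_short_bout_raises(self):
        with pytest.raises(ValueError, match="4 samples"):
            ft.sensor_bout_features([1.0, 2.0], fs_hz=10.0)


class TestSensorMealFeatures:
    def test_two_identical_bouts_average_and_total(self):
        fs = 16.0
        t = np.arange(64) / fs
        bout = np.sin(2 * np.pi * 1.5 * t)
        samples = np.concatenate([bout, np.zeros(32), bout])
        sig = SensorSignal(fs, samples, [(0.0, 4.0), (6.0, 10.0)])
        vals = ft.sensor_features(sig)
        single = ft.sensor_bout_features(bout, fs)
        for name in ft.SENSOR_BOUT_FEATURES:
            assert vals[f"avg_{name}"] == pytest.approx(single[name])
            assert vals[f"total_{name}"] == pytest.approx(2 * single[name])
        assert vals["n_bouts"] == 2.0

    def test_no_bouts_imputes_23_zeros(self):
        vals = ft.sensor_features(None)
        assert len(vals) == 23
        assert all(v == 0.0 for v in vals.values())


class TestExtractAll:
    def test_feature_count_and_targets(self):
        rng = np.random.default_rng(8)
        meal = make_random_meal(rng)
        fv, tv = ft.extract_all(meal)
        assert len(fv) == 57
        assert list(fv.values) == list(ft.FEATURE_REGISTRY)
        assert tv.mass_g == pytest.approx(sum(m for _, m, _ in meal.bites))

    def test_single_food_energy(self):
        meal = simple_meal([0.0, 30.0], swallows=[5.0, 35.0],
                           masses=[100.0, 200.0])
        meal.foods = [Food("biscuit", 2.0)]
        _, tv = ft.extract_all(meal)
        assert tv.energy_kcal == pytest.approx(600.0)

    def test_sd_squared_equals_var_for_every_pair(self):
        rng = np.random.default_rng(13)
        pairs = [(n, n.replace("sd_", "var_")) for n in ft.FEATURE_REGISTRY
                 if n.startswith("sd_")]
        assert len(pairs) == 7
        for _ in range(10):
            fv, _ = ft.extract_all(make_random_meal(rng))
            for sd_name, var_name in pairs:
                assert fv.values[sd_name] ** 2 == pytest.approx(
                    fv.values[var_name], rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scale_equivariance_of_event_features(self, seed):
        """Scaling all event times by c divides rates by c, multiplies
        durations by c, squares accordingly for variances, and leaves
        counts unchanged."""
        c = 3.0
        rng = np.random.default_rng(seed)
        meal = make_random_meal(rng, with_sensor=False)
        scaled = MealRecord(
            meal.subject_id, meal.meal_id,
            [(t * c, m, f) for t, m, f in meal.bites],
            [(s * c, e * c, n) for s, e, n in meal.chew_sequences],
            [t * c for t in meal.swallows],
            meal.foods,
        )
        base, _ = ft.extract_all(meal)
        got, _ = ft.extract_all(scaled)
        counts = ["total_bite", "chews_seq", "total_chews", "total_swallow",
                  "avg_chews_perSeq", "sd_chews_perSeq", "var_chews_perSeq",
                  "avg_swl_bite", "sd_swl_bite", "var_swl_bite"]
        rates = ["avg_biteRate_Teating", "avg_biteRate_Tmeal", "avg_IBF",
                 "sd_IBF", "chewRate_Tchewing", "avg_chewRate_Teating",
                 "avg_chewRate_Tmeal", "avg_chewRate_perSeq",
                 "sd_chewRate_perSeq", "avg_swlRate_Teating",
                 "avg_swlRate_Tmeal", "avg_ISF", "sd_ISF"]
        rate_vars = ["var_IBF", "var_chewRate_perSeq", "var_ISF"]
        durs = ["total_chews_du", "avg_chews_du_perSeq", "sd_chews_du_perSeq",
                "total_pause_du", "avg_pause_du", "sd_pause_du"]
        dur_vars = ["var_chews_du_perSeq", "var_pause_du"]
        for n in counts:
            assert got.values[n] == pytest.approx(base.values[n], rel=1e-9)
        for n in rates:
            assert got.values[n] == pytest.approx(base.values[n] / c, rel=1e-9)
        for n in rate_vars:
            assert got.values[n] == pytest.approx(base.values[n] / c**2, rel=1e-9)
        for n in durs:
            assert got.values[n] == pytest.approx(base.values[n] * c, rel=1e-9)
        for n in dur_vars:
            assert got.values[n] == pytest.approx(base.values[n] * c**2, rel=1e-9)


def test_features_match_brute_force_on_random_meals():
    """Every one of the 57 features agrees with an independent loop-based
    recomputation on randomized meals (including sensor bouts)."""
    rng = np.random.default_rng(42)
    for i in range(30):
        meal = make_random_meal(rng, with_sensor=True)
        fv, _ = ft.extract_all(meal)
        expected = oracles.all_features(meal)
        for name in ft.FEATURE_REGISTRY:
            assert fv.values[name] == pytest.approx(
                expected[name], rel=1e-8, abs=1e-10), f"meal {i}: {name}"
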