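import numpy as np
import pytest

from mealmetry.synth import (
    Food,
    MealRecord,
    SensorSignal,
    SubjectPriors,
    SyntheticConfig,
    generate_cohort,
)

SOLID = Food("biscuit", 4.5, False, 0.6)
SOFT = Food("yogurt", 0.8, False, 0.2)
LIQUID = Food("juice", 0.45, True, 0.0)


def make_random_meal(rng: np.random.Generator, with_sensor: bool = True,
                     subject_id: str = "S01", meal_id: str = "M1") -> MealRecord:
    """A small, hand-assembled meal with short sensor bouts.

    Built event-by-event (bite -> chews -> swallows -> pause) so every
    chewing sequence lies between its bite and the next; bouts are kept to
    <= ~130 samples so the naive DFT oracle stays fast.
    """
    fs = 16.0
    foods = [SOLID, SOFT, LIQUID]
    n_bites = int(rng.integers(3, 9))
    bites, seqs, swallows = [], [], []
    t = float(rng.uniform(0, 2))
    for _ in range(n_bites):
        food = foods[int(rng.integers(0, len(foods)))]
        mass = float(rng.uniform(2, 25))
        bites.append((t, mass, food.food_id))
        if food.is_liquid:
            end = t + 0.4
            swallows.append(end)
        else:
            start = t + 0.3
            dur = float(rng.uniform(2.0, 8.0))
            count = int(rng.integers(4, 20))
            seqs.append((start, start + dur, count))
            end = start + dur
            for _k in range(int(rng.integers(1, 4))):
                end += float(rng.uniform(0.3, 1.0))
                swallows.append(end)
        t = end + float(rng.uniform(0.5, 12.0))
    sensor = None
    if with_sensor:
        meal_end = max([b[0] for b in bites] + [e for _, e, _ in seqs] + swallows)
        n = int(np.ceil((meal_end + 1) * fs))
        samples = rng.normal(0, 0.02, n)
        windows = []
        for s, e, _ in seqs:
            i0, i1 = int(round(s * fs)), int(round(e * fs))
            tt = np.arange(i1 - i0) / fs
            samples[i0:i1] += 0.4 * np.sin(2 * np.pi * 1.5 * tt + rng.uniform(0, 6))
            windows.append((s, e))
        sensor = SensorSignal(fs_hz=fs, samples=samples, bout_windows=windows)
    meal = MealRecord(subject_id, meal_id, bites, seqs, swallows,
                      foods, sensor)
    meal.validate()
    return meal


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 2 meals with sensors, fixed seed."""
    cfg = SyntheticConfig(n_subjects=6, meals_per_subject=2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    from mealmetry.features import features_table

    records, _ = small_cohort
    return features_table(records)


def recovery_config(seed: int, noise_sd: float = 30.0) -> SyntheticConfig:
    """Study condition for coefficient recovery: a shared mean bite mass
    (no between-subject spread) and meal-level Gaussian mass noise, so
    total mass = beta * total_bite + iid noise exactly."""
    return SyntheticConfig(
        n_subjects=28,
        meals_per_subject=4,
        subject_priors=SubjectPriors(bite_mass_mean_g=10.0, bite_mass_sd_g=0.0),
        noise_sd_mass_g=noise_sd,
        with_sensor=False,
        seed=seed,
    )
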