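"""Synthetic meal-microstructure cohorts.

Generates cohorts of :class:`MealRecord` that emulate a laboratory ingestive
behaviour study: each of ``n_subjects`` participants eats ``meals_per_subject``
meals built from a small food library (solids and liquids with known energy
density).  Every meal is an ordered event stream of bites (with weighed mass),
chewing sequences, swallows and pauses, optionally accompanied by a
chewing-sensor amplitude trace whose bouts align with the chewing sequences.

The generator is the ground-truth authority for downstream testing: total meal
mass is exactly the sum of per-bite masses, energy is exactly mass times
energy density per food, and mass is linearly coupled to bite count so the
regression stage has a recoverable signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Food",
    "SensorSignal",
    "MealRecord",
    "TargetVector",
    "SubjectProfile",
    "SubjectPriors",
    "MealSpec",
    "SyntheticConfig",
    "ConfigError",
    "generate_sensor_bout",
    "generate_meal",
    "generate_cohort",
    "DEFAULT_FOOD_LIBRARY",
]


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Food:
    """One food item: energy density in kcal/g, liquid flag, texture hardness in [0, 1]."""

    food_id: str
    energy_density_kcal_per_g: float
    is_liquid: bool = False
    hardness: float = 0.5

    def __post_init__(self) -> None:
        if self.energy_density_kcal_per_g < 0:
            raise ConfigError(
                f"energy_density_kcal_per_g must be >= 0 for food {self.food_id!r}"
            )
        if not (0.0 <= self.hardness <= 1.0):
            raise ConfigError(f"hardness must be in [0, 1] for food {self.food_id!r}")


@dataclass
class SensorSignal:
    """A chewing-sensor amplitude trace with bout windows aligned to chewing sequences."""

    fs_hz: float
    samples: np.ndarray
    bout_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)
        dur = len(self.samples) / self.fs_hz
        for start, end in self.bout_windows:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"bout window ({start}, {end}) outside signal duration {dur:.6g} s"
                )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass
class MealRecord:
    """One meal's annotated event streams plus food composition.

    ``bites`` are (time_s, mass_g, food_id) in time order; ``chew_sequences``
    are (start_s, end_s, chew_count); ``swallows`` are times in seconds.  All
    clocks are meal-local (0 = first event).
    """

    subject_id: str
    meal_id: str
    bites: list[tuple[float, float, str]]
    chew_sequences: list[tuple[float, float, int]]
    swallows: list[float]
    foods: list[Food]
    sensor: Optional[SensorSignal] = None

    def validate(self) -> None:
        food_ids = {f.food_id for f in self.foods}
        for t, mass, fid in self.bites:
            if t < 0:
                raise ValueError(f"bite time {t} is negative")
            if mass < 0:
                raise ValueError(f"bite mass {mass} is negative")
            if fid not in food_ids:
                raise ValueError(f"bite food_id {fid!r} not present in foods")
        for start, end, count in self.chew_sequences:
            if start < 0 or end <= start:
                raise ValueError(f"chew sequence ({start}, {end}) not a forward interval")
            if count < 1:
                raise ValueError(f"chew_count {count} < 1")
        for t in self.swallows:
            if t < 0:
                raise ValueError(f"swallow time {t} is negative")
        for name, times in (
            ("bites", [b[0] for b in self.bites]),
            ("chew_sequences", [s[0] for s in self.chew_sequences]),
            ("swallows", list(self.swallows)),
        ):
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} not time-ordered")
        if self.sensor is not None and len(self.sensor.bout_windows) != len(
            self.chew_sequences
        ):
            raise ValueError("sensor bout_windows count != chew_sequences count")

    @property
    def mass_g(self) -> float:
        return float(sum(m for _, m, _ in self.bites))

    def consumed_mass_by_food(self) -> dict[str, float]:
        out: dict[str, float] = {f.food_id: 0.0 for f in self.foods}
        for _, mass, fid in self.bites:
            out[fid] += mass
        return out

    @property
    def energy_kcal(self) -> float:
        density = {f.food_id: f.energy_density_kcal_per_g for f in self.foods}
        return float(
            sum(mass * density[fid] for fid, mass in self.consumed_mass_by_food().items())
        )

    def target(self) -> "TargetVector":
        return TargetVector(mass_g=self.mass_g, energy_kcal=self.energy_kcal)


@dataclass(frozen=True)
class TargetVector:
    """The two dependent quantities for a meal: total mass (g) and energy (kcal)."""

    mass_g: float
    energy_kcal: float


@dataclass(frozen=True)
class SubjectPriors:
    """Between-subject distributions for eating-style parameters.

    Chew rate is normal (Hz); mean bite mass and mean pause are lognormal on
    the stated mean with the stated between-subject SD; bites per meal is the
    subject's Poisson mean.
    """

    chew_rate_mean_hz: float = 1.4
    chew_rate_sd_hz: float = 0.15
    bite_mass_mean_g: float = 10.0
    bite_mass_sd_g: float = 2.0
    bite_mass_within_cv: float = 0.3
    pause_mean_s: float = 6.0
    pause_sd_s: float = 2.0
    bites_per_meal_mean: float = 22.0
    bites_per_meal_sd: float = 5.0
    sensor_amplitude_mean: float = 0.5
    sensor_amplitude_sd: float = 0.1
    chews_per_g_per_hardness: float = 2.5


@dataclass(frozen=True)
class SubjectProfile:
    """One subject's eating-style parameters, drawn once from the priors."""

    subject_id: str
    chew_rate_hz: float
    bite_mass_g: float
    pause_mean_s: float
    bites_per_meal: float
    sensor_amplitude: float
    chews_per_g_per_hardness: float = 2.5


@dataclass(frozen=True)
class MealSpec:
    """Per-meal inputs to :func:`generate_meal`."""

    meal_id: str
    foods: tuple[Food, ...]
    noise_sd_mass_g: float = 0.0
    bite_mass_within_cv: float = 0.3
    with_sensor: bool = True
    sensor_fs_hz: float = 100.0
    sensor_noise_sd: float = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level configuration; defaults mirror a 28-subject, 4-meal design."""

    n_subjects: int = 28
    meals_per_subject: int = 4
    food_library: tuple[Food, ...] = ()
    subject_priors: SubjectPriors = SubjectPriors()
    noise_sd_mass_g: float = 30.0
    sensor_fs_hz: float = 100.0
    sensor_noise_sd: float = 0.05
    with_sensor: bool = True
    foods_per_meal: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2 (leave-one-subject-out needs >= 2)")
        if self.meals_per_subject < 1:
            raise ConfigError("meals_per_subject must be >= 1")
        if self.noise_sd_mass_g < 0:
            raise ConfigError("noise_sd_mass_g must be >= 0")
        if self.sensor_fs_hz <= 0:
            raise ConfigError("sensor_fs_hz must be > 0")
        if self.foods_per_meal < 1:
            raise ConfigError("foods_per_meal must be >= 1")
        if self.food_library:
            for f in self.food_library:
                if f.energy_density_kcal_per_g < 0:
                    raise ConfigError(
                        f"food_library energy density < 0 for {f.food_id!r}"
                    )

    def resolved_food_library(self) -> tuple[Food, ...]:
        return self.food_library if self.food_library else DEFAULT_FOOD_LIBRARY


#: A small mixed solid/liquid cafeteria-style library (kcal/g from typical
#: composition tables); hardness is a unitless texture scale driving chews/g.
DEFAULT_FOOD_LIBRARY: tuple[Food, ...] = (
    Food("sandwich", 2.4, False, 0.55),
    Food("salad", 0.7, False, 0.35),
    Food("pasta", 1.6, False, 0.40),
    Food("pizza", 2.7, False, 0.60),
    Food("apple", 0.52, False, 0.70),
    Food("cookie", 4.8, False, 0.50),
    Food("banana", 0.89, False, 0.25),
    Food("juice", 0.45, True, 0.0),
    Food("soda", 0.41, True, 0.0),
    Food("water", 0.0, True, 0.0),
)


# ---------------------------------------------------------------------------
# Sensor waveform
# ---------------------------------------------------------------------------


def generate_sensor_bout(
    duration_s: float,
    chew_rate_hz: float,
    amplitude: float,
    noise_sd: float,
    fs_hz: float,
    rng: np.random.Generator,
    *,
    phase: float = 0.0,
    taper: float = 0.0,
) -> np.ndarray:
    """Quasi-periodic chewing-bout waveform: a sinusoid at the chewing rate
    plus white noise.

    ``taper`` in [0, 0.5) applies a raised-cosine ramp over that fraction of
    the bout at each edge (0 keeps a flat envelope).  Requires
    ``fs_hz >= 4 * chew_rate_hz`` so the chewing peak is resolvable.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fs_hz < 4 * chew_rate_hz:
        raise ValueError(
            f"fs_hz={fs_hz} too low for chew_rate_hz={chew_rate_hz} "
            "(need fs_hz >= 4 * chew_rate_hz)"
        )
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    x = amplitude * np.sin(2 * np.pi * chew_rate_hz * t + phase)
    if taper > 0:
        ramp_n = int(round(taper * n))
        if ramp_n > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
            env = np.ones(n)
            env[:ramp_n] = ramp
            env[n - ramp_n :] = ramp[::-1]
            x = x * env
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x


# ---------------------------------------------------------------------------
# Meal and cohort generation
# ---------------------------------------------------------------------------

_CHEW_LATENCY_S = 0.3  # bite -> first chew
_SWALLOW_SPACING_S = 0.8
_MIN_PAUSE_S = 0.2


def generate_meal(
    profile: SubjectProfile, meal_spec: MealSpec, rng: np.random.Generator
) -> MealRecord:
    """Generate one meal's event streams for a subject.

    Each bite is followed by a chewing sequence (for solid foods) whose chew
    count scales with hardness x bite mass, then 1-3 swallows, then an
    exponential pause before the next bite.  Liquid bites skip chewing and go
    straight to a swallow.  The meal's total mass is the subject's mean bite
    mass times the bite count plus Gaussian noise, distributed over bites with
    lognormal weights, so total mass is linearly coupled to bite count by
    construction.
    """
    if not meal_spec.foods:
        raise ValueError("meal_spec.foods must not be empty")
    foods = list(meal_spec.foods)
    food_by_id = {f.food_id: f for f in foods}

    n_bites = max(5, int(rng.poisson(profile.bites_per_meal)))
    ideal_total = n_bites * profile.bite_mass_g
    total = ideal_total
    if meal_spec.noise_sd_mass_g > 0:
        total = max(1.0, total + rng.normal(0.0, meal_spec.noise_sd_mass_g))
    if meal_spec.bite_mass_within_cv > 0:
        w = rng.lognormal(0.0, meal_spec.bite_mass_within_cv, n_bites)
    else:
        w = np.ones(n_bites)
    masses = total * w / w.sum()
    bite_food_ids = [foods[i].food_id for i in rng.integers(0, len(foods), n_bites)]

    bites: list[tuple[float, float, str]] = []
    chew_sequences: list[tuple[float, float, int]] = []
    swallows: list[float] = []
    t = 0.0
    for k in range(n_bites):
        food = food_by_id[bite_food_ids[k]]
        bites.append((t, float(masses[k]), food.food_id))
        if food.is_liquid:
            bout_end = t + 0.5
            swallows.append(bout_end)
        else:
            start = t + _CHEW_LATENCY_S
            base = profile.chews_per_g_per_hardness * food.hardness * masses[k]
            count = max(1, int(round(base)) + int(rng.poisson(2.0)))
            end = start + count / profile.chew_rate_hz
            chew_sequences.append((start, end, count))
            n_sw = int(rng.integers(1, 4))
            sw_times = [end + 0.2 + i * _SWALLOW_SPACING_S for i in range(n_sw)]
            swallows.extend(sw_times)
            bout_end = sw_times[-1]
        pause = max(_MIN_PAUSE_S, rng.exponential(profile.pause_mean_s))
        t = bout_end + pause

    sensor = None
    if meal_spec.with_sensor:
        meal_end = max(
            [b[0] for b in bites]
            + [s[1] for s in chew_sequences]
            + list(swallows)
        )
        fs = meal_spec.sensor_fs_hz
        n = int(math.ceil((meal_end + 1.0) * fs))
        samples = np.zeros(n)
        windows: list[tuple[float, float]] = []
        for start, end, _count in chew_sequences:
            bout = generate_sensor_bout(
                end - start,
                profile.chew_rate_hz,
                profile.sensor_amplitude,
                meal_spec.sensor_noise_sd,
                fs,
                rng,
                phase=float(rng.uniform(0, 2 * np.pi)),
                taper=0.1,
            )
            i0 = int(round(start * fs))
            samples[i0 : i0 + len(bout)] = bout
            windows.append((start, end))
        sensor = SensorSignal(fs_hz=fs, samples=samples, bout_windows=windows)

    record = MealRecord(
        subject_id=profile.subject_id,
        meal_id=meal_spec.meal_id,
        bites=bites,
        chew_sequences=chew_sequences,
        swallows=swallows,
        foods=foods,
        sensor=sensor,
    )
    record.validate()
    return record


def _draw_profiles(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[SubjectProfile]:
    p = config.subject_priors
    profiles = []
    for i in range(config.n_subjects):
        chew_rate = max(0.5, rng.normal(p.chew_rate_mean_hz, p.chew_rate_sd_hz))
        if p.bite_mass_sd_g > 0:
            cv = p.bite_mass_sd_g / p.bite_mass_mean_g
            sigma = math.sqrt(math.log(1 + cv**2))
            mu = math.log(p.bite_mass_mean_g) - sigma**2 / 2
            bite_mass = float(rng.lognormal(mu, sigma))
        else:
            bite_mass = p.bite_mass_mean_g
        if p.pause_sd_s > 0:
            cv = p.pause_sd_s / p.pause_mean_s
            sigma = math.sqrt(math.log(1 + cv**2))
            mu = math.log(p.pause_mean_s) - sigma**2 / 2
            pause_mean = float(rng.lognormal(mu, sigma))
        else:
            pause_mean = p.pause_mean_s
        bites_mean = max(5.0, rng.normal(p.bites_per_meal_mean, p.bites_per_meal_sd))
        amplitude = max(0.05, rng.normal(p.sensor_amplitude_mean, p.sensor_amplitude_sd))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                chew_rate_hz=float(chew_rate),
                bite_mass_g=bite_mass,
                pause_mean_s=pause_mean,
                bites_per_meal=float(bites_mean),
                sensor_amplitude=float(amplitude),
                chews_per_g_per_hardness=p.chews_per_g_per_hardness,
            )
        )
    return profiles


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[MealRecord], pd.DataFrame]:
    """Generate a full cohort of meals plus a table of ground-truth targets.

    All randomness flows from ``config.seed``; subject-level parameters are
    drawn before any meal so adding meals never perturbs subject profiles.
    Returns the records and a DataFrame with columns
    (subject_id, meal_id, mass_g, energy_kcal).
    """
    rng = np.random.default_rng(config.seed)
    library = config.resolved_food_library()
    profiles = _draw_profiles(config, rng)

    records: list[MealRecord] = []
    rows = []
    for profile in profiles:
        for j in range(config.meals_per_subject):
            k = min(config.foods_per_meal, len(library))
            idx = rng.choice(len(library), size=k, replace=False)
            # guarantee at least one solid food so meals normally have chews
            foods = [library[int(i)] for i in idx]
            if all(f.is_liquid for f in foods) and any(
                not f.is_liquid for f in library
            ):
                solids = [f for f in library if not f.is_liquid]
                foods[0] = solids[int(rng.integers(0, len(solids)))]
            spec = MealSpec(
                meal_id=f"M{j + 1}",
                foods=tuple(foods),
                noise_sd_mass_g=config.noise_sd_mass_g,
                bite_mass_within_cv=config.subject_priors.bite_mass_within_cv,
                with_sensor=config.with_sensor,
                sensor_fs_hz=config.sensor_fs_hz,
                sensor_noise_sd=config.sensor_noise_sd,
            )
            meal = generate_meal(profile, spec, rng)
            records.append(meal)
            tv = meal.target()
            rows.append(
                {
                    "subject_id": meal.subject_id,
                    "meal_id": meal.meal_id,
                    "mass_g": tv.mass_g,
                    "energy_kcal": tv.energy_kcal,
                }
            )
    return records, pd.DataFrame(rows)
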