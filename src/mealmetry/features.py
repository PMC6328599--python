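"""Meal-level feature extraction from annotated event streams and sensor bouts.

Fifty-seven independent features are computed per meal, partitioned into five
groups: 6 bite, 15 chew, 9 swallow, 4 pause and 23 sensor features.  The two
dependent quantities (total mass in g, total energy in kcal) are computed
alongside.  Feature names follow the conventions of the wearable
ingestive-behaviour literature (e.g. ``avg_biteRate_Teating`` = bite count
over eating time, ``sd_ISF`` = SD of instantaneous swallowing frequency).

Duration conventions
--------------------
* meal duration: first event time to last event time;
* eating duration: meal duration minus total pause duration;
* chewing duration: sum of chewing-sequence durations.

An *ingestion bout* runs from a bite to the later of its chewing-sequence end
and its last following swallow before the next bite; pauses are the gaps
between consecutive bouts, so ``total_pause_du + eating_du = meal_du``
exactly.

Degenerate statistics (SD/variance over fewer than two items, instantaneous
frequencies with fewer than two events, a meal with no chewing sequences or
no sensor bouts) are imputed as 0, with a warning logged, so feature vectors
stay finite for modeling.  All SDs and variances are sample statistics
(n - 1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import MealRecord, SensorSignal, TargetVector

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_REGISTRY",
    "FEATURE_GROUPS",
    "FAMILY_POOLS",
    "SENSOR_BOUT_FEATURES",
    "REGISTRY_VERSION",
    "DurationTriple",
    "FeatureVector",
    "instantaneous_frequencies",
    "durations",
    "bite_features",
    "chew_features",
    "swallow_features",
    "pause_features",
    "sensor_bout_features",
    "sensor_features",
    "extract_all",
    "features_table",
]

REGISTRY_VERSION = "1.0"

BITE_FEATURES = (
    "total_bite",
    "avg_biteRate_Teating",
    "avg_biteRate_Tmeal",
    "avg_IBF",
    "sd_IBF",
    "var_IBF",
)

CHEW_FEATURES = (
    "chews_seq",
    "total_chews",
    "total_chews_du",
    "chewRate_Tchewing",
    "avg_chewRate_Teating",
    "avg_chewRate_Tmeal",
    "avg_chews_perSeq",
    "sd_chews_perSeq",
    "var_chews_perSeq",
    "avg_chews_du_perSeq",
    "sd_chews_du_perSeq",
    "var_chews_du_perSeq",
    "avg_chewRate_perSeq",
    "sd_chewRate_perSeq",
    "var_chewRate_perSeq",
)

SWALLOW_FEATURES = (
    "total_swallow",
    "avg_swlRate_Teating",
    "avg_swlRate_Tmeal",
    "avg_ISF",
    "sd_ISF",
    "var_ISF",
    "avg_swl_bite",
    "sd_swl_bite",
    "var_swl_bite",
)

PAUSE_FEATURES = (
    "total_pause_du",
    "avg_pause_du",
    "sd_pause_du",
    "var_pause_du",
)

#: Per-bout sensor-signal features (EMG-style time/frequency descriptors).
SENSOR_BOUT_FEATURES = (
    "zero_crossings",
    "crossing_du",
    "Total_Entropy",
    "Waveform_Length",
    "mean_Amplitude",
    "var_Amplitude",
    "autocorr_period",
    "pwr",
    "pwr_dB",
    "Spectral_energy",
    "max_freq",
)

SENSOR_FEATURES = (
    tuple(f"avg_{name}" for name in SENSOR_BOUT_FEATURES)
    + tuple(f"total_{name}" for name in SENSOR_BOUT_FEATURES)
    + ("n_bouts",)
)

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "bite": BITE_FEATURES,
    "chew": CHEW_FEATURES,
    "swallow": SWALLOW_FEATURES,
    "pause": PAUSE_FEATURES,
    "sensor": SENSOR_FEATURES,
}

FEATURE_REGISTRY: tuple[str, ...] = (
    BITE_FEATURES + CHEW_FEATURES + SWALLOW_FEATURES + PAUSE_FEATURES + SENSOR_FEATURES
)

#: Candidate pools for the five model families.
FAMILY_POOLS: dict[str, tuple[str, ...]] = {
    "full": FEATURE_REGISTRY,
    "bite": BITE_FEATURES,
    "chew": CHEW_FEATURES,
    "swallow": SWALLOW_FEATURES,
    "sensor": SENSOR_FEATURES,
}

PWR_DB_FLOOR = -120.0  # imputed dB for a zero-power bout
_ENTROPY_BINS = 100


@dataclass(frozen=True)
class DurationTriple:
    """Meal, eating and chewing durations in seconds."""

    meal_du_s: float
    eating_du_s: float
    chewing_du_s: float

    def __post_init__(self) -> None:
        if not (
            -1e-9 <= self.chewing_du_s <= self.eating_du_s + 1e-9
            and self.eating_du_s <= self.meal_du_s + 1e-9
        ):
            raise ValueError(
                "durations must satisfy 0 <= chewing <= eating <= meal "
                f"(got {self.chewing_du_s}, {self.eating_du_s}, {self.meal_du_s})"
            )


@dataclass
class FeatureVector:
    """The 57 named independent features for one meal, in registry order."""

    subject_id: str
    meal_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_REGISTRY:
            raise ValueError("feature names/order must match the canonical registry")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=(self.subject_id, self.meal_id))


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _mean_sd_var(values) -> tuple[float, float, float]:
    """Sample mean/SD/variance, imputing 0 for fewer than two items."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return 0.0, 0.0, 0.0
    if arr.size == 1:
        return float(arr[0]), 0.0, 0.0
    var = float(np.var(arr, ddof=1))
    return float(arr.mean()), float(np.sqrt(var)), var


def instantaneous_frequencies(event_times) -> np.ndarray:
    """Reciprocal of each inter-event interval, in Hz.

    Requires at least two strictly increasing times; duplicate timestamps
    raise (the frequency would be infinite).
    """
    t = np.asarray(event_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 events for instantaneous frequencies")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("event times must be strictly increasing (duplicate timestamp?)")
    return 1.0 / dt


def _event_times(meal: MealRecord) -> list[float]:
    times = [b[0] for b in meal.bites] + list(meal.swallows)
    for s, e, _ in meal.chew_sequences:
        times.extend((s, e))
    return times


def _ingestion_bouts(meal: MealRecord) -> list[tuple[float, float]]:
    """(start, end) of each ingestion bout, one per bite.

    A bout runs from its bite to the later of the chewing-sequence ends and
    swallow times that fall before the next bite (clamped at the bite itself
    if nothing follows).
    """
    bite_times = [b[0] for b in meal.bites]
    n = len(bite_times)
    bouts = []
    for k, t in enumerate(bite_times):
        nxt = bite_times[k + 1] if k + 1 < n else np.inf
        end = t
        for s, e, _ in meal.chew_sequences:
            if t <= s < nxt:
                end = max(end, e)
        for sw in meal.swallows:
            if t <= sw < nxt:
                end = max(end, sw)
        bouts.append((t, end))
    return bouts


def durations(meal: MealRecord) -> tuple[DurationTriple, list[float]]:
    """Compute the duration triple and the list of pause durations."""
    if not meal.bites:
        raise ValueError("meal has no bites")
    times = _event_times(meal)
    meal_du = max(times) - min(times)
    bouts = _ingestion_bouts(meal)
    pauses = [
        max(0.0, bouts[k + 1][0] - bouts[k][1]) for k in range(len(bouts) - 1)
    ]
    total_pause = float(sum(pauses))
    chewing = float(sum(e - s for s, e, _ in meal.chew_sequences))
    return DurationTriple(meal_du, meal_du - total_pause, chewing), pauses


# ---------------------------------------------------------------------------
# Event-stream feature groups
# ---------------------------------------------------------------------------


def bite_features(meal: MealRecord, dur: DurationTriple) -> dict[str, float]:
    """Six bite features: count, two rates, and instantaneous-frequency stats."""
    if not meal.bites:
        raise ValueError("meal has no bites")
    if dur.eating_du_s <= 0 or dur.meal_du_s <= 0:
        raise ValueError("eating and meal durations must be positive for bite rates")
    n = len(meal.bites)
    times = [b[0] for b in meal.bites]
    if n >= 2:
        avg, sd, var = _mean_sd_var(instantaneous_frequencies(times))
    else:
        logger.warning("meal %s/%s: single bite, IBF stats imputed 0",
                       meal.subject_id, meal.meal_id)
        avg = sd = var = 0.0
    return {
        "total_bite": float(n),
        "avg_biteRate_Teating": n / dur.eating_du_s,
        "avg_biteRate_Tmeal": n / dur.meal_du_s,
        "avg_IBF": avg,
        "sd_IBF": sd,
        "var_IBF": var,
    }


def chew_features(meal: MealRecord, dur: DurationTriple) -> dict[str, float]:
    """Fifteen chew features from the per-sequence counts, durations and rates."""
    seqs = meal.chew_sequences
    if not seqs:
        logger.warning("meal %s/%s: no chewing sequences, chew features imputed 0",
                       meal.subject_id, meal.meal_id)
        return {name: 0.0 for name in CHEW_FEATURES}
    counts = np.array([c for _, _, c in seqs], dtype=float)
    durs = np.array([e - s for s, e, _ in seqs], dtype=float)
    if np.any(durs <= 0):
        raise ValueError("chewing sequence with zero duration")
    rates = counts / durs
    total_chews = float(counts.sum())
    total_du = float(durs.sum())
    avg_c, sd_c, var_c = _mean_sd_var(counts)
    avg_d, sd_d, var_d = _mean_sd_var(durs)
    avg_r, sd_r, var_r = _mean_sd_var(rates)
    return {
        "chews_seq": float(len(seqs)),
        "total_chews": total_chews,
        "total_chews_du": total_du,
        "chewRate_Tchewing": total_chews / total_du,
        "avg_chewRate_Teating": total_chews / dur.eating_du_s,
        "avg_chewRate_Tmeal": total_chews / dur.meal_du_s,
        "avg_chews_perSeq": avg_c,
        "sd_chews_perSeq": sd_c,
        "var_chews_perSeq": var_c,
        "avg_chews_du_perSeq": avg_d,
        "sd_chews_du_perSeq": sd_d,
        "var_chews_du_perSeq": var_d,
        "avg_chewRate_perSeq": avg_r,
        "sd_chewRate_perSeq": sd_r,
        "var_chewRate_perSeq": var_r,
    }


def swallow_features(meal: MealRecord, dur: DurationTriple) -> dict[str, float]:
    """Nine swallow features: count, rates, ISF stats, swallows-per-bite stats.

    The bite gaps for ``swl_bite`` are half-open intervals [bite_k, bite_{k+1})
    with the final gap running to the meal end (inclusive).
    """
    sw = list(meal.swallows)
    out = {name: 0.0 for name in SWALLOW_FEATURES}
    if not sw:
        logger.warning("meal %s/%s: no swallows, swallow features imputed 0",
                       meal.subject_id, meal.meal_id)
        return out
    out["total_swallow"] = float(len(sw))
    out["avg_swlRate_Teating"] = len(sw) / dur.eating_du_s
    out["avg_swlRate_Tmeal"] = len(sw) / dur.meal_du_s
    if len(sw) >= 2:
        avg, sd, var = _mean_sd_var(instantaneous_frequencies(sw))
    else:
        avg = sd = var = 0.0
    out["avg_ISF"], out["sd_ISF"], out["var_ISF"] = avg, sd, var

    bite_times = [b[0] for b in meal.bites]
    meal_end = max(_event_times(meal))
    edges = bite_times + [np.inf]
    counts = []
    for k in range(len(bite_times)):
        lo, hi = edges[k], edges[k + 1]
        if np.isinf(hi):
            c = sum(1 for t in sw if lo <= t <= meal_end)
        else:
            c = sum(1 for t in sw if lo <= t < hi)
        counts.append(float(c))
    out["avg_swl_bite"], out["sd_swl_bite"], out["var_swl_bite"] = _mean_sd_var(counts)
    return out


def pause_features(meal: MealRecord) -> dict[str, float]:
    """Four pause features over the gaps between consecutive ingestion bouts."""
    _, pauses = durations(meal)
    if not pauses:
        return {name: 0.0 for name in PAUSE_FEATURES}
    _, sd, var = _mean_sd_var(pauses)
    return {
        "total_pause_du": float(sum(pauses)),
        "avg_pause_du": float(np.mean(pauses)),
        "sd_pause_du": sd,
        "var_pause_du": var,
    }


# ---------------------------------------------------------------------------
# Sensor features
# ---------------------------------------------------------------------------


def sensor_bout_features(bout, fs_hz: float) -> dict[str, float]:
    """Eleven time/frequency descriptors of one chewing-bout waveform.

    zero_crossings counts crossings of the bout mean; crossing_du is the mean
    time between consecutive crossings; Total_Entropy is the Shannon entropy
    (natural log) of a 100-bin amplitude histogram; Waveform_Length is the
    summed absolute first difference; autocorr_period is the lag of the first
    local autocorrelation maximum after lag 0; Spectral_energy is the squared
    spectrum magnitude normalised so it equals the signal energy (Parseval);
    max_freq excludes the DC bin.
    """
    x = np.asarray(bout, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("sensor bout must have at least 4 samples")
    z = x - x.mean()

    sign_change = z[:-1] * z[1:] < 0
    crossings = int(np.count_nonzero(sign_change))
    if crossings >= 2:
        idx = np.flatnonzero(sign_change)
        # linear interpolation of the fractional crossing position
        frac = idx + z[idx] / (z[idx] - z[idx + 1])
        crossing_du = float(np.mean(np.diff(frac)) / fs_hz)
    else:
        crossing_du = 0.0

    if np.ptp(x) > 0:
        counts, _ = np.histogram(x, bins=_ENTROPY_BINS)
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0

    wl = float(np.abs(np.diff(x)).sum())
    mean_amp = float(np.abs(x).mean())
    var_amp = float(np.var(x, ddof=1))

    r = np.correlate(z, z, mode="full")[n - 1 :]
    period = 0.0
    for lag in range(1, n - 1):
        if r[lag] > r[lag - 1] and r[lag] >= r[lag + 1]:
            period = lag / fs_hz
            break

    pwr = float(np.mean(x**2))
    pwr_db = 10 * np.log10(pwr) if pwr > 0 else PWR_DB_FLOOR
    spec = np.fft.fft(x)
    spectral_energy = float((np.abs(spec) ** 2).sum() / n)  # == sum(x**2)
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    k = 1 + int(np.argmax(mag[1:]))
    max_freq = float(freqs[k])

    return {
        "zero_crossings": float(crossings),
        "crossing_du": crossing_du,
        "Total_Entropy": entropy,
        "Waveform_Length": wl,
        "mean_Amplitude": mean_amp,
        "var_Amplitude": var_amp,
        "autocorr_period": period,
        "pwr": pwr,
        "pwr_dB": float(pwr_db),
        "Spectral_energy": spectral_energy,
        "max_freq": max_freq,
    }


def sensor_features(signal: SensorSignal | None) -> dict[str, float]:
    """Meal-level sensor features: per-bout averages and totals plus bout count.

    A meal with no bouts (liquid-only, or no sensor) gets all 23 imputed as 0.
    """
    out = {name: 0.0 for name in SENSOR_FEATURES}
    if signal is None or not signal.bout_windows:
        return out
    fs = signal.fs_hz
    per_bout: list[dict[str, float]] = []
    for start, end in signal.bout_windows:
        i0 = int(round(start * fs))
        i1 = int(round(end * fs))
        per_bout.append(sensor_bout_features(signal.samples[i0:i1], fs))
    for name in SENSOR_BOUT_FEATURES:
        vals = np.array([b[name] for b in per_bout])
        out[f"avg_{name}"] = float(vals.mean())
        out[f"total_{name}"] = float(vals.sum())
    out["n_bouts"] = float(len(per_bout))
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def extract_all(meal: MealRecord) -> tuple[FeatureVector, TargetVector]:
    """Compute the full 57-feature vector and the (mass, energy) targets."""
    dur, _ = durations(meal)
    values: dict[str, float] = {}
    values.update(bite_features(meal, dur))
    values.update(chew_features(meal, dur))
    values.update(swallow_features(meal, dur))
    values.update(pause_features(meal))
    values.update(sensor_features(meal.sensor))
    ordered = {name: values[name] for name in FEATURE_REGISTRY}
    fv = FeatureVector(meal.subject_id, meal.meal_id, ordered)
    return fv, meal.target()


def features_table(records) -> pd.DataFrame:
    """Feature + target table for a cohort: one row per meal.

    Columns: subject_id, meal_id, the 57 registry features, mass_g, energy_kcal.
    """
    rows = []
    for meal in records:
        fv, tv = extract_all(meal)
        row = {"subject_id": fv.subject_id, "meal_id": fv.meal_id}
        row.update(fv.values)
        row["mass_g"] = tv.mass_g
        row["energy_kcal"] = tv.energy_kcal
        rows.append(row)
    return pd.DataFrame(rows)
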