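"""Independent brute-force oracles for the test suite.

Everything here is written with plain Python loops (``math``/``cmath``, no
vectorised shortcuts and no calls into the package's feature or modeling
code), so agreement between the package and these functions is a genuine
two-route check.  The naive DFT is O(n^2); callers keep bouts short.
"""

from __future__ import annotations

import cmath
import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_var(xs):
    if len(xs) < 2:
        return 0.0
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)


def mean_sd_var(xs):
    if len(xs) == 0:
        return 0.0, 0.0, 0.0
    v = sample_var(xs)
    return mean(xs), math.sqrt(v), v


# ---------------------------------------------------------------------------
# Event-stream features
# ---------------------------------------------------------------------------


def inst_freqs(times):
    return [1.0 / (b - a) for a, b in zip(times, times[1:])]


def ingestion_bouts(meal):
    bite_times = [b[0] for b in meal.bites]
    bouts = []
    for k, t in enumerate(bite_times):
        nxt = bite_times[k + 1] if k + 1 < len(bite_times) else math.inf
        end = t
        for s, e, _ in meal.chew_sequences:
            if t <= s < nxt and e > end:
                end = e
        for sw in meal.swallows:
            if t <= sw < nxt and sw > end:
                end = sw
        bouts.append((t, end))
    return bouts


def durations_and_pauses(meal):
    times = [b[0] for b in meal.bites] + list(meal.swallows)
    for s, e, _ in meal.chew_sequences:
        times += [s, e]
    meal_du = max(times) - min(times)
    bouts = ingestion_bouts(meal)
    pauses = [max(0.0, bouts[k + 1][0] - bouts[k][1]) for k in range(len(bouts) - 1)]
    total_pause = sum(pauses)
    chewing = sum(e - s for s, e, _ in meal.chew_sequences)
    return meal_du, meal_du - total_pause, chewing, pauses


def event_features(meal):
    """All 34 bite/chew/swallow/pause features by direct loops."""
    meal_du, eating_du, _chewing_du, pauses = durations_and_pauses(meal)
    out = {}

    bite_times = [b[0] for b in meal.bites]
    n_bites = len(bite_times)
    out["total_bite"] = float(n_bites)
    out["avg_biteRate_Teating"] = n_bites / eating_du
    out["avg_biteRate_Tmeal"] = n_bites / meal_du
    ibf = inst_freqs(bite_times) if n_bites >= 2 else []
    out["avg_IBF"], out["sd_IBF"], out["var_IBF"] = mean_sd_var(ibf)

    seqs = meal.chew_sequences
    if seqs:
        counts = [float(c) for _, _, c in seqs]
        durs = [e - s for s, e, _ in seqs]
        rates = [c / d for c, d in zip(counts, durs)]
        out["chews_seq"] = float(len(seqs))
        out["total_chews"] = sum(counts)
        out["total_chews_du"] = sum(durs)
        out["chewRate_Tchewing"] = sum(counts) / sum(durs)
        out["avg_chewRate_Teating"] = sum(counts) / eating_du
        out["avg_chewRate_Tmeal"] = sum(counts) / meal_du
        (out["avg_chews_perSeq"], out["sd_chews_perSeq"],
         out["var_chews_perSeq"]) = mean_sd_var(counts)
        (out["avg_chews_du_perSeq"], out["sd_chews_du_perSeq"],
         out["var_chews_du_perSeq"]) = mean_sd_var(durs)
        (out["avg_chewRate_perSeq"], out["sd_chewRate_perSeq"],
         out["var_chewRate_perSeq"]) = mean_sd_var(rates)
    else:
        for k in ("chews_seq", "total_chews", "total_chews_du", "chewRate_Tchewing",
                  "avg_chewRate_Teating", "avg_chewRate_Tmeal", "avg_chews_perSeq",
                  "sd_chews_perSeq", "var_chews_perSeq", "avg_chews_du_perSeq",
                  "sd_chews_du_perSeq", "var_chews_du_perSeq", "avg_chewRate_perSeq",
                  "sd_chewRate_perSeq", "var_chewRate_perSeq"):
            out[k] = 0.0

    sw = list(meal.swallows)
    if sw:
        out["total_swallow"] = float(len(sw))
        out["avg_swlRate_Teating"] = len(sw) / eating_du
        out["avg_swlRate_Tmeal"] = len(sw) / meal_du
        isf = inst_freqs(sw) if len(sw) >= 2 else []
        out["avg_ISF"], out["sd_ISF"], out["var_ISF"] = mean_sd_var(isf)
        all_times = [b[0] for b in meal.bites] + sw
        for s, e, _ in meal.chew_sequences:
            all_times += [s, e]
        meal_end = max(all_times)
        counts = []
        for k, t in enumerate(bite_times):
            if k + 1 < n_bites:
                c = sum(1 for x in sw if t <= x < bite_times[k + 1])
            else:
                c = sum(1 for x in sw if t <= x <= meal_end)
            counts.append(float(c))
        (out["avg_swl_bite"], out["sd_swl_bite"],
         out["var_swl_bite"]) = mean_sd_var(counts)
    else:
        for k in ("total_swallow", "avg_swlRate_Teating", "avg_swlRate_Tmeal",
                  "avg_ISF", "sd_ISF", "var_ISF", "avg_swl_bite", "sd_swl_bite",
                  "var_swl_bite"):
            out[k] = 0.0

    if pauses:
        out["total_pause_du"] = sum(pauses)
        out["avg_pause_du"] = mean(pauses)
        _, out["sd_pause_du"], out["var_pause_du"] = mean_sd_var(pauses)
    else:
        for k in ("total_pause_du", "avg_pause_du", "sd_pause_du", "var_pause_du"):
            out[k] = 0.0
    return out


# ---------------------------------------------------------------------------
# Sensor bout features (naive DFT; keep bouts short)
# ---------------------------------------------------------------------------


def bout_features(x, fs):
    x = [float(v) for v in x]
    n = len(x)
    m = mean(x)
    z = [v - m for v in x]

    cross_pos = []
    for i in range(n - 1):
        if z[i] * z[i + 1] < 0:
            cross_pos.append(i + z[i] / (z[i] - z[i + 1]))
    crossings = len(cross_pos)
    if crossings >= 2:
        gaps = [b - a for a, b in zip(cross_pos, cross_pos[1:])]
        crossing_du = mean(gaps) / fs
    else:
        crossing_du = 0.0

    lo, hi = min(x), max(x)
    if hi > lo:
        counts = [0] * 100
        for v in x:
            idx = int((v - lo) / (hi - lo) * 100)
            counts[min(idx, 99)] += 1
        entropy = -sum(c / n * math.log(c / n) for c in counts if c)
    else:
        entropy = 0.0

    wl = sum(abs(b - a) for a, b in zip(x, x[1:]))
    mean_amp = mean([abs(v) for v in x])
    var_amp = sample_var(x)

    r = [sum(z[i] * z[i + lag] for i in range(n - lag)) for lag in range(n)]
    period = 0.0
    for lag in range(1, n - 1):
        if r[lag] > r[lag - 1] and r[lag] >= r[lag + 1]:
            period = lag / fs
            break

    pwr = mean([v * v for v in x])
    pwr_db = 10 * math.log10(pwr) if pwr > 0 else -120.0
    spectral_energy = sum(v * v for v in x)
    best_k, best_mag = 1, -1.0
    for k in range(1, n // 2 + 1):
        X = sum(x[j] * cmath.exp(-2j * math.pi * k * j / n) for j in range(n))
        magk = abs(X)
        if magk > best_mag + 1e-12 * max(best_mag, 1.0):
            best_k, best_mag = k, magk
    max_freq = best_k * fs / n

    return {
        "zero_crossings": float(crossings),
        "crossing_du": crossing_du,
        "Total_Entropy": entropy,
        "Waveform_Length": wl,
        "mean_Amplitude": mean_amp,
        "var_Amplitude": var_amp,
        "autocorr_period": period,
        "pwr": pwr,
        "pwr_dB": pwr_db,
        "Spectral_energy": spectral_energy,
        "max_freq": max_freq,
    }


def sensor_meal_features(signal):
    names = ("zero_crossings", "crossing_du", "Total_Entropy", "Waveform_Length",
             "mean_Amplitude", "var_Amplitude", "autocorr_period", "pwr", "pwr_dB",
             "Spectral_energy", "max_freq")
    out = {}
    if signal is None or not signal.bout_windows:
        for nm in names:
            out[f"avg_{nm}"] = 0.0
            out[f"total_{nm}"] = 0.0
        out["n_bouts"] = 0.0
        return out
    per = []
    for start, end in signal.bout_windows:
        i0 = int(round(start * signal.fs_hz))
        i1 = int(round(end * signal.fs_hz))
        per.append(bout_features(signal.samples[i0:i1], signal.fs_hz))
    for nm in names:
        vals = [b[nm] for b in per]
        out[f"avg_{nm}"] = mean(vals)
        out[f"total_{nm}"] = sum(vals)
    out["n_bouts"] = float(len(per))
    return out


def all_features(meal):
    out = event_features(meal)
    out.update(sensor_meal_features(meal.sensor))
    return out


# ---------------------------------------------------------------------------
# Regression oracle: explicit normal equations
# ---------------------------------------------------------------------------


def zero_intercept_ols(X, y):
    """(beta, se, root_mse) from hand-built normal equations.

    X is a list of rows; solves (X'X) beta = X'y by Gauss-Jordan with the
    matrix inverse kept for the standard errors.
    """
    n = len(X)
    p = len(X[0])
    xtx = [[sum(X[i][a] * X[i][b] for i in range(n)) for b in range(p)]
           for a in range(p)]
    xty = [sum(X[i][a] * y[i] for i in range(n)) for a in range(p)]
    inv = _invert(xtx)
    beta = [sum(inv[a][b] * xty[b] for b in range(p)) for a in range(p)]
    sse = sum((y[i] - sum(X[i][a] * beta[a] for a in range(p))) ** 2
              for i in range(n))
    sigma2 = sse / (n - p)
    se = [math.sqrt(sigma2 * inv[a][a]) for a in range(p)]
    return beta, se, math.sqrt(sigma2)


def _invert(a):
    n = len(a)
    aug = [list(row) + [1.0 if i == j else 0.0 for j in range(n)]
           for i, row in enumerate(a)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(aug[r][col]))
        if abs(aug[piv][col]) < 1e-300:
            raise ValueError("singular matrix")
        aug[col], aug[piv] = aug[piv], aug[col]
        d = aug[col][col]
        aug[col] = [v / d for v in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0.0:
                f = aug[r][col]
                aug[r] = [v - f * w for v, w in zip(aug[r], aug[col])]
    return [row[n:] for row in aug]
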