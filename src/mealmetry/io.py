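"""File formats: annotation events, food composition, sensor traces, reports.

All formats are plain-text, UTF-8, comma-delimited with a decimal point
(locale-independent).  Numbers are serialized with ``%.17g`` so round-trips
are lossless for doubles.  Times are seconds from meal start; masses are
grams; energies are kcal.

Annotation CSV
    header ``subject_id,meal_id,event_type,start_s,end_s,value,food_id``;
    ``event_type`` is one of bite / chew_seq / swallow.  Bite rows carry the
    bite mass (g) in ``value`` and a ``food_id``; chew_seq rows carry the
    chew count in ``value`` and an ``end_s``; swallow rows carry only
    ``start_s``.  One file may hold many meals keyed by (subject_id,
    meal_id); each meal's rows are contiguous and time-sorted.

Food CSV
    ``subject_id,meal_id,food_id,consumed_mass_g,energy_density_kcal_per_g,is_liquid``.

Sensor CSV (one meal per file)
    a ``fs_hz`` line, ``bout,start_s,end_s`` lines, a ``samples`` marker and
    one amplitude per line.

Report
    JSON holding coefficient tables (ModelFit) and agreement statistics
    (EvaluationReport) keyed by model name.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .synth import Food, MealRecord, SensorSignal

__all__ = [
    "ParseError",
    "read_annotations",
    "write_annotations",
    "read_foods",
    "write_foods",
    "read_sensor",
    "write_sensor",
    "write_report",
    "read_report",
]

EVENT_TYPES = ("bite", "chew_seq", "swallow")
_ANNOTATION_HEADER = [
    "subject_id",
    "meal_id",
    "event_type",
    "start_s",
    "end_s",
    "value",
    "food_id",
]
_FOOD_HEADER = [
    "subject_id",
    "meal_id",
    "food_id",
    "consumed_mass_g",
    "energy_density_kcal_per_g",
    "is_liquid",
]


class ParseError(ValueError):
    """A file failed to parse; the message carries the row number."""


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def write_annotations(records: Iterable[MealRecord], path) -> None:
    """Write the event streams of many meals to one annotation CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_ANNOTATION_HEADER)
        for meal in records:
            rows = []
            for t, mass, fid in meal.bites:
                rows.append((t, ["bite", _fmt(t), "", _fmt(mass), fid]))
            for s, e, count in meal.chew_sequences:
                rows.append((s, ["chew_seq", _fmt(s), _fmt(e), str(int(count)), ""]))
            for t in meal.swallows:
                rows.append((t, ["swallow", _fmt(t), "", "", ""]))
            rows.sort(key=lambda r: r[0])
            for _, fields in rows:
                w.writerow([meal.subject_id, meal.meal_id, *fields])


def read_annotations(path, foods_path=None) -> list[MealRecord]:
    """Parse an annotation CSV into MealRecords (without sensor traces).

    If ``foods_path`` is given, food composition (energy density, liquid
    flag) is attached from the food CSV; otherwise foods are built from the
    bite food_ids with zero energy density.
    """
    foods_map: dict[tuple[str, str], list[Food]] = {}
    if foods_path is not None:
        foods_map = _read_foods_map(foods_path)

    order: list[tuple[str, str]] = []
    bites: dict[tuple[str, str], list] = {}
    seqs: dict[tuple[str, str], list] = {}
    swallows: dict[tuple[str, str], list] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _ANNOTATION_HEADER:
            raise ParseError(f"unexpected annotation header: {header}")
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_ANNOTATION_HEADER):
                raise ParseError(f"row {i}: expected {len(_ANNOTATION_HEADER)} fields")
            sid, mid, etype, start_s, end_s, value, food_id = row
            if etype not in EVENT_TYPES:
                raise ParseError(f"row {i}: unknown event_type {etype!r}")
            try:
                t = float(start_s)
            except ValueError as exc:
                raise ParseError(f"row {i}: bad start_s {start_s!r}") from exc
            if t < 0:
                raise ParseError(f"row {i}: negative time {t}")
            key = (sid, mid)
            if key not in bites:
                order.append(key)
                bites[key], seqs[key], swallows[key] = [], [], []
            if etype == "bite":
                bites[key].append((t, float(value), food_id))
            elif etype == "chew_seq":
                end = float(end_s)
                if end <= t:
                    raise ParseError(f"row {i}: chew_seq end {end} <= start {t}")
                seqs[key].append((t, end, int(float(value))))
            else:
                swallows[key].append(t)

    records = []
    for key in order:
        sid, mid = key
        meal_foods = foods_map.get(key)
        if meal_foods is None:
            meal_foods = [
                Food(fid, 0.0) for fid in dict.fromkeys(f for _, _, f in bites[key])
            ]
        meal = MealRecord(
            subject_id=sid,
            meal_id=mid,
            bites=sorted(bites[key], key=lambda b: b[0]),
            chew_sequences=sorted(seqs[key], key=lambda s: s[0]),
            swallows=sorted(swallows[key]),
            foods=meal_foods,
        )
        meal.validate()
        records.append(meal)
    return records


# ---------------------------------------------------------------------------
# Foods
# ---------------------------------------------------------------------------


def write_foods(records: Iterable[MealRecord], path) -> None:
    """Write per-meal food composition and consumed masses."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FOOD_HEADER)
        for meal in records:
            consumed = meal.consumed_mass_by_food()
            for food in meal.foods:
                w.writerow(
                    [
                        meal.subject_id,
                        meal.meal_id,
                        food.food_id,
                        _fmt(consumed.get(food.food_id, 0.0)),
                        _fmt(food.energy_density_kcal_per_g),
                        "1" if food.is_liquid else "0",
                    ]
                )


def _read_foods_map(path) -> dict[tuple[str, str], list[Food]]:
    out: dict[tuple[str, str], list[Food]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _FOOD_HEADER:
            raise ParseError(f"unexpected food header: {header}")
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            sid, mid, fid, mass, dens, liq = row
            if float(mass) < 0 or float(dens) < 0:
                raise ParseError(f"row {i}: negative mass or energy density")
            out.setdefault((sid, mid), []).append(
                Food(fid, float(dens), liq == "1")
            )
    return out


def read_foods(path) -> dict[tuple[str, str], list[Food]]:
    """Food composition per (subject_id, meal_id)."""
    return _read_foods_map(path)


# ---------------------------------------------------------------------------
# Sensor traces
# ---------------------------------------------------------------------------


def write_sensor(signal: SensorSignal, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"fs_hz,{_fmt(signal.fs_hz)}\n")
        fh.write(f"n_bouts,{len(signal.bout_windows)}\n")
        for start, end in signal.bout_windows:
            fh.write(f"bout,{_fmt(start)},{_fmt(end)}\n")
        fh.write("samples\n")
        fh.writelines(_fmt(x) + "\n" for x in signal.samples)


def read_sensor(path) -> SensorSignal:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    try:
        tag, fs_str = lines[0].split(",")
        assert tag == "fs_hz"
        fs = float(fs_str)
    except (IndexError, ValueError, AssertionError) as exc:
        raise ParseError("sensor file must start with an fs_hz line") from exc
    if fs <= 0:
        raise ParseError(f"fs_hz must be > 0, got {fs}")
    tag, n_bouts = lines[1].split(",")
    if tag != "n_bouts":
        raise ParseError("second line must declare n_bouts")
    n_b = int(n_bouts)
    windows = []
    for k in range(n_b):
        tag, s, e = lines[2 + k].split(",")
        if tag != "bout":
            raise ParseError(f"line {3 + k}: expected a bout line")
        windows.append((float(s), float(e)))
    if lines[2 + n_b] != "samples":
        raise ParseError("missing 'samples' marker")
    samples = np.array([float(x) for x in lines[3 + n_b :] if x], dtype=float)
    return SensorSignal(fs_hz=fs, samples=samples, bout_windows=windows)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(evaluations: Mapping[str, object], model_fits: Mapping[str, object],
                 path) -> None:
    """Write a structured JSON report of model fits and agreement statistics.

    ``evaluations`` and ``model_fits`` are keyed by model name (e.g.
    ``"bite/mass_g"``); values are EvaluationReport / ModelFit dataclasses.
    An empty mapping produces a valid empty report.
    """
    doc = {
        "units": {"mass": "g", "energy": "kcal", "time": "s"},
        "models": {
            name: {
                "fit": _to_jsonable(asdict(fit)) if fit is not None else None,
                "evaluation": _to_jsonable(asdict(evaluations[name]))
                if evaluations.get(name) is not None
                else None,
            }
            for name, fit in model_fits.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def read_report(path) -> dict:
    """Load a report JSON back as plain dicts (for round-trip checks)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
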