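"""Meal-centered window construction from raw event streams.

Converts per-subject event logs into analyzable meal windows: short CGM gaps
are linearly interpolated (runs of five or fewer missing readings), each
logged meal gets a [-120, 0) pre-meal channel matrix and a post-meal glucose
series through +210 minutes on the 5-minute grid, the bolus mediator is
aggregated over the closed [-120, +60] window, and windows violating the
exclusion rules (overlapping meals, unimputed missingness, CGM artifacts,
post-mediator-window boluses) are dropped with a per-reason tally.  The
chronological split assigns the first 65% of each subject's days to training
and computes standardization statistics on training windows only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import GRID_MINUTES, HORIZONS
from .synthetic import MealEventLog, ValidationError, _snap

__all__ = [
    "MealWindow",
    "SplitSpec",
    "GapReport",
    "interpolate_gaps",
    "extract_windows",
    "apply_exclusions",
    "aggregate_mediator",
    "chronological_split",
    "standardize_pre_matrices",
    "windows_to_table",
    "write_windows",
    "read_windows",
]

PRE_ROWS = 24                      # [-120, 0) on the 5-minute grid
CHANNELS = ("glucose", "steps", "basal", "carbs", "heart_rate")
POST_POINTS = 210 // GRID_MINUTES  # grid points after the meal, +5..+210
MAX_INTERP_RUN = 5                 # runs of >= 6 missing readings stay missing
MEDIATOR_WINDOW = (-120, 60)       # closed interval, minutes relative to meal
OVERLAP_MIN = 90                   # meals closer than this exclude each other
ARTIFACT_RANGE = (20.0, 500.0)     # plausible CGM range, mg/dL
ARTIFACT_JUMP = 50.0               # max plausible change per 5 minutes, mg/dL
DAY_MIN = 1440


@dataclass
class MealWindow:
    """One analyzable meal-centered window."""

    subject_id: str
    cohort: str
    meal_type: str
    meal_time: int                       # snapped, minutes from study start
    pre_matrix: np.ndarray               # (24, 5): glucose, steps, basal, carbs, HR
    Z: float                             # carbohydrates, grams
    M: float                             # bolus insulin in [-120, +60], units
    G0: float                            # glucose at meal time, mg/dL
    delta_g: dict[int, float]            # horizon -> excursion, mg/dL
    post_glucose: np.ndarray             # (43,): glucose at 0, +5, ..., +210
    exclusion_flags: set[str] = field(default_factory=set)
    #: bolus event times relative to the meal, within [-120, +210]
    bolus_times_rel: np.ndarray = field(default_factory=lambda: np.empty(0))
    raw_meal_time: float = 0.0

    def validate(self) -> None:
        if self.pre_matrix.shape != (PRE_ROWS, len(CHANNELS)):
            raise ValidationError(
                f"pre_matrix must be {PRE_ROWS}x{len(CHANNELS)}, "
                f"got {self.pre_matrix.shape}")
        if self.M < 0:
            raise ValidationError("mediator M must be >= 0")
        if self.Z <= 0:
            raise ValidationError("treatment Z must be > 0")


@dataclass
class SplitSpec:
    """Per-subject chronological day boundary and training-only channel stats."""

    train_fraction_days: float
    day_boundary: dict[str, int]         # subject -> last training day index
    channel_mean: np.ndarray             # (5,)
    channel_sd: np.ndarray               # (5,)


@dataclass
class GapReport:
    filled_runs: list[tuple[int, int]]       # (start index, run length) interpolated
    unfilled_runs: list[tuple[int, int]]     # runs left missing (>=6 or no flank)


# ---------------------------------------------------------------------------

def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs, i, n = [], 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def interpolate_gaps(cgm: pd.DataFrame) -> tuple[pd.DataFrame, GapReport]:
    """Fill short CGM gaps by linear interpolation.

    Runs of at most five consecutive missing readings with observed values on
    both sides are filled linearly; longer runs, and runs touching the series
    boundary, are left missing and reported.
    """
    values = cgm["glucose"].to_numpy(float).copy()
    times = cgm["timestamp_min"].to_numpy()
    if np.any(np.diff(times) <= 0) or np.any(times % GRID_MINUTES != 0):
        raise ValidationError("CGM timestamps must be strictly increasing "
                              "multiples of 5 minutes")
    report = GapReport(filled_runs=[], unfilled_runs=[])
    for start, length in _missing_runs(np.isnan(values)):
        end = start + length
        has_flanks = start > 0 and end < len(values)
        if length <= MAX_INTERP_RUN and has_flanks:
            lo, hi = values[start - 1], values[end]
            frac = np.arange(1, length + 1) / (length + 1)
            values[start:end] = lo + frac * (hi - lo)
            report.filled_runs.append((start, length))
        else:
            report.unfilled_runs.append((start, length))
    return cgm.assign(glucose=values), report


def _grid_series(df: pd.DataFrame, value_col: str, grid: np.ndarray) -> np.ndarray:
    """Align a (timestamp_min, value) series to the CGM grid (NaN off-grid)."""
    s = df.set_index("timestamp_min")[value_col]
    return s.reindex(grid).to_numpy(float)


def _basal_on_grid(basal: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    """Evaluate the basal step function at grid times."""
    b = basal.sort_values("timestamp_min")
    idx = np.searchsorted(b["timestamp_min"].to_numpy(), grid, side="right") - 1
    rates = b["rate_u_hr"].to_numpy(float)
    out = np.where(idx >= 0, rates[np.clip(idx, 0, None)], np.nan)
    return out


def aggregate_mediator(window: MealWindow | int, boluses: pd.DataFrame) -> float:
    """Total bolus insulin (units) in the closed [-120, +60] minute window.

    Accepts a :class:`MealWindow` or a snapped meal time directly.
    """
    t0 = window.meal_time if isinstance(window, MealWindow) else int(window)
    units = boluses["units"].to_numpy(float)
    if np.any(units < 0):
        raise ValidationError("negative bolus units")
    times = boluses["timestamp_min"].to_numpy(float)
    lo, hi = t0 + MEDIATOR_WINDOW[0], t0 + MEDIATOR_WINDOW[1]
    sel = (times >= lo) & (times <= hi)
    return float(units[sel].sum())


def extract_windows(log: MealEventLog) -> list[MealWindow]:
    """One window per logged meal (pass the log through
    :func:`interpolate_gaps` first).

    Off-grid meal times are snapped to the nearest grid point (ties round
    down).  Meals within 120 minutes of the log start or 210 minutes of its
    end are flagged ``incomplete``.
    """
    cgm = log.cgm
    grid = cgm["timestamp_min"].to_numpy()
    glucose = cgm["glucose"].to_numpy(float)
    n = len(grid)
    start_t = int(grid[0])

    hr = _grid_series(log.heart_rate, "bpm", grid) if log.heart_rate is not None \
        else np.zeros(n)
    steps = _grid_series(log.steps, "count", grid) if log.steps is not None \
        else np.zeros(n)
    basal = _basal_on_grid(log.basal, grid) if log.basal is not None else np.zeros(n)
    carbs_chan = np.zeros(n)
    snapped_all = _snap(log.meals["timestamp_min"].to_numpy())
    for t_snap, grams in zip(snapped_all, log.meals["carbs_g"].to_numpy(float)):
        i = (t_snap - start_t) // GRID_MINUTES
        if 0 <= i < n:
            carbs_chan[i] += grams

    windows = []
    for (_, meal), t_snap in zip(log.meals.iterrows(), snapped_all):
        i0 = int((t_snap - start_t) // GRID_MINUTES)
        flags: set[str] = set()
        if i0 < PRE_ROWS or i0 + POST_POINTS >= n:
            flags.add("incomplete")
            pre = np.full((PRE_ROWS, len(CHANNELS)), np.nan)
            post = np.full(POST_POINTS + 1, np.nan)
            g0 = np.nan
        else:
            sl = slice(i0 - PRE_ROWS, i0)
            pre = np.column_stack([glucose[sl], steps[sl], basal[sl],
                                   carbs_chan[sl], hr[sl]])
            post = glucose[i0:i0 + POST_POINTS + 1].copy()
            g0 = float(glucose[i0])
        delta = {t: float(post[t // GRID_MINUTES] - g0) if not flags else np.nan
                 for t in HORIZONS}
        if log.boluses is not None and len(log.boluses):
            rel = log.boluses["timestamp_min"].to_numpy(float) - t_snap
            rel = rel[(rel >= -120) & (rel <= 210)]
            m_val = aggregate_mediator(int(t_snap), log.boluses)
        else:
            rel = np.empty(0)
            m_val = 0.0
        windows.append(MealWindow(
            subject_id=log.subject_id, cohort=log.cohort,
            meal_type=str(meal["meal_type"]), meal_time=int(t_snap),
            pre_matrix=pre, Z=float(meal["carbs_g"]), M=m_val, G0=g0,
            delta_g=delta, post_glucose=post, exclusion_flags=flags,
            bolus_times_rel=rel, raw_meal_time=float(meal["timestamp_min"]),
        ))
    return windows


def _flag_artifacts(values: np.ndarray) -> bool:
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < ARTIFACT_RANGE[0]
                        or finite.max() > ARTIFACT_RANGE[1]):
        return True
    diffs = np.abs(np.diff(values))
    return bool(np.any(diffs[np.isfinite(diffs)] > ARTIFACT_JUMP))


def apply_exclusions(
    windows: Sequence[MealWindow],
    *,
    max_missing: int = 0,
) -> tuple[list[MealWindow], dict[str, int]]:
    """Drop windows violating the exclusion rules; tally counts per reason.

    Rules: meals under 90 minutes from an adjacent meal (both members of the
    pair are dropped); more than ``max_missing`` unimputed missing readings
    anywhere in [-120, +210]; artifact readings (outside 20-500 mg/dL or
    jumps above 50 mg/dL per 5 min); any bolus event in (+60, +210]; windows
    flagged incomplete at extraction.
    """
    by_subject: dict[str, list[MealWindow]] = {}
    for w in windows:
        by_subject.setdefault(w.subject_id, []).append(w)
    for subj_windows in by_subject.values():
        subj_windows.sort(key=lambda w: w.raw_meal_time)
        for a, b in zip(subj_windows, subj_windows[1:]):
            if b.raw_meal_time - a.raw_meal_time < OVERLAP_MIN:
                a.exclusion_flags.add("overlap")
                b.exclusion_flags.add("overlap")

    for w in windows:
        if "incomplete" in w.exclusion_flags:
            continue
        full = np.concatenate([w.pre_matrix[:, 0], w.post_glucose])
        if np.isnan(full).sum() > max_missing:
            w.exclusion_flags.add("missing")
        elif _flag_artifacts(full):
            w.exclusion_flags.add("artifact")
        if np.any((w.bolus_times_rel > MEDIATOR_WINDOW[1])
                  & (w.bolus_times_rel <= 210)):
            w.exclusion_flags.add("late_bolus")

    tally = {"incomplete": 0, "overlap": 0, "missing": 0, "artifact": 0,
             "late_bolus": 0, "retained": 0}
    retained = []
    for w in windows:
        if w.exclusion_flags:
            for f in w.exclusion_flags:
                tally[f] += 1
        else:
            tally["retained"] += 1
            w.validate()
            retained.append(w)
    tally["excluded"] = len(windows) - len(retained)
    return retained, tally


# ---------------------------------------------------------------------------

def chronological_split(
    windows: Sequence[MealWindow], fraction: float = 0.65,
) -> tuple[SplitSpec, list[MealWindow], list[MealWindow]]:
    """Per-subject day-level chronological split.

    The first ``ceil(fraction * n_days)`` distinct days of each subject go to
    training.  Standardization statistics (per-channel mean/SD) are computed
    from training windows only.
    """
    days: dict[str, list[int]] = {}
    for w in windows:
        days.setdefault(w.subject_id, []).append(w.meal_time // DAY_MIN)
    boundary = {}
    for subj, ds in days.items():
        uniq = sorted(set(ds))
        if len(uniq) < 2:
            raise ValidationError(
                f"subject {subj!r} has a single day of data; cannot split")
        n_train = math.ceil(fraction * len(uniq))
        boundary[subj] = uniq[min(n_train, len(uniq)) - 1]

    train = [w for w in windows if w.meal_time // DAY_MIN <= boundary[w.subject_id]]
    test = [w for w in windows if w.meal_time // DAY_MIN > boundary[w.subject_id]]
    if not train:
        raise ValidationError("empty training partition")
    stack = np.stack([w.pre_matrix for w in train])       # (n, 24, 5)
    mean = stack.mean(axis=(0, 1))
    sd = stack.std(axis=(0, 1))
    sd = np.where(sd < 1e-12, 1.0, sd)
    spec = SplitSpec(train_fraction_days=fraction, day_boundary=boundary,
                     channel_mean=mean, channel_sd=sd)
    return spec, train, test


def standardize_pre_matrices(windows: Sequence[MealWindow],
                             spec: SplitSpec) -> np.ndarray:
    """Stack pre-meal matrices standardized with the training statistics."""
    stack = np.stack([w.pre_matrix for w in windows])
    return (stack - spec.channel_mean) / spec.channel_sd


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def windows_to_table(windows: Iterable[MealWindow]) -> pd.DataFrame:
    rows = []
    for i, w in enumerate(windows):
        row = {"window_id": i, "subject_id": w.subject_id, "cohort": w.cohort,
               "meal_type": w.meal_type, "meal_time": w.meal_time,
               "Z": w.Z, "M": w.M, "G0": w.G0,
               "flags": "|".join(sorted(w.exclusion_flags))}
        for t in HORIZONS:
            row[f"delta_g_{t}"] = w.delta_g[t]
        rows.append(row)
    return pd.DataFrame(rows)


_DATA_DICT = """\
column,description,units
window_id,sequential window identifier,-
subject_id,study participant label,-
cohort,cohort label (2018 or 2020),-
meal_type,breakfast / lunch / dinner / snack,-
meal_time,snapped meal time from study start,minutes
Z,meal carbohydrate content (treatment),grams
M,bolus insulin aggregated over [-120 +60] (mediator),units
G0,glucose at meal time (baseline),mg/dL
delta_g_<t>,glucose excursion G(t) - G(0) at horizon t,mg/dL
flags,pipe-separated exclusion flags (empty = retained),-
pre_<channel>_<row>,pre-meal matrix entry (rows 0..23 span [-120 0)),channel units
"""


def write_windows(windows: Sequence[MealWindow], outdir: str | Path) -> None:
    """Write the windows table, the flattened pre-meal matrices, and a data
    dictionary as delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows_to_table(windows).to_csv(outdir / "windows.csv", index=False)
    cols, data = [], []
    for ch_i, ch in enumerate(CHANNELS):
        for r in range(PRE_ROWS):
            cols.append(f"pre_{ch}_{r}")
    for w in windows:
        data.append(w.pre_matrix.T.reshape(-1))
    pre = pd.DataFrame(np.array(data) if data else np.empty((0, len(cols))),
                       columns=cols)
    pre.insert(0, "window_id", range(len(windows)))
    pre.to_csv(outdir / "pre_matrices.csv", index=False)
    post = pd.DataFrame(
        np.array([w.post_glucose for w in windows]) if windows else
        np.empty((0, POST_POINTS + 1)),
        columns=[f"post_{5 * i}" for i in range(POST_POINTS + 1)])
    post.insert(0, "window_id", range(len(windows)))
    post.to_csv(outdir / "post_glucose.csv", index=False)
    (outdir / "data_dictionary.csv").write_text(_DATA_DICT)


def read_windows(indir: str | Path) -> list[MealWindow]:
    indir = Path(indir)
    table = pd.read_csv(indir / "windows.csv", dtype={"cohort": str})
    pre = pd.read_csv(indir / "pre_matrices.csv").set_index("window_id")
    post = pd.read_csv(indir / "post_glucose.csv").set_index("window_id")
    out = []
    for _, row in table.iterrows():
        wid = row.window_id
        pre_mat = pre.loc[wid].to_numpy(float).reshape(len(CHANNELS), PRE_ROWS).T
        flags = set(str(row.flags).split("|")) if isinstance(row.flags, str) \
            and row.flags else set()
        out.append(MealWindow(
            subject_id=row.subject_id, cohort=str(row.cohort),
            meal_type=row.meal_type, meal_time=int(row.meal_time),
            pre_matrix=pre_mat, Z=row.Z, M=row.M, G0=row.G0,
            delta_g={t: row[f"delta_g_{t}"] for t in HORIZONS},
            post_glucose=post.loc[wid].to_numpy(float),
            exclusion_flags=flags))
    return out
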