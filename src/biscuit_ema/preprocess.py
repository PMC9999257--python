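"""From raw EMA exports to the predictor matrix and shifted binge criterion.

The pipeline here mirrors standard idiographic EMA preparation: derive the
objective binge-eating criterion from signal- and event-contingent reports
(large amount AND loss of control), pad each day's last prompt with an
empty row so no model step regresses across the overnight gap, shift the
criterion one prompt back in time (predicting the next ~2.5 h), and build
44 candidate predictors: 31 antecedent items, the unshifted binge
indicator (autoregressive term), 6 sinusoid/cosinusoid cycles (8, 12,
24 h) of cumulative scheduled time, and 6 time-of-day dummies.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_ema import ITEM_NAMES, ParticipantDataset

AR_PREDICTOR = "binge_now"
CYCLE_PERIODS: tuple[float, ...] = (8.0, 12.0, 24.0)
CYCLE_PREDICTORS: list[str] = [
    f"{kind}_{int(p)}h" for p in CYCLE_PERIODS for kind in ("sin", "cos")
]
SLOT_LABELS: tuple[str, ...] = (
    "morning",
    "late_morning",
    "early_afternoon",
    "afternoon",
    "evening",
    "late_evening",
)
DUMMY_PREDICTORS: list[str] = [f"tod_{label}" for label in SLOT_LABELS]

#: canonical column order of the 44 candidate predictors
PREDICTOR_NAMES: list[str] = ITEM_NAMES + [AR_PREDICTOR] + CYCLE_PREDICTORS + DUMMY_PREDICTORS

META_COLUMNS = ["timestamp", "day", "slot", "cum_hours", "answered", "is_padding"]
CRITERION = "y_next"


def _as_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"yes", "true", "1"}:
        return True
    if s in {"no", "false", "0"}:
        return False
    return None


def derive_binge_outcome(
    meal_type, answered: bool, events_in_window: pd.DataFrame | None
) -> float:
    """Binary objective-binge indicator for one prompt.

    1 iff the prompt's meal was reported as a binge OR some event report in
    the prompt's window satisfies both criteria of an objective episode
    (excessive amount AND loss of control); 0 otherwise; NaN when the
    prompt is unanswered and no qualifying event exists.  Event reports
    with a missing criterion field are rejected with a warning.
    """
    qualifying = False
    if events_in_window is not None and len(events_in_window):
        for _, ev in events_in_window.iterrows():
            exc = _as_bool(ev.get("excessive_amount"))
            loc = _as_bool(ev.get("loss_of_control"))
            if exc is None or loc is None:
                warnings.warn(
                    "event report with missing excessive/loss-of-control field rejected",
                    stacklevel=2,
                )
                continue
            if exc and loc:
                qualifying = True
    if qualifying:
        return 1.0
    if not answered:
        return np.nan
    return 1.0 if meal_type == "binge" else 0.0


def assign_events_to_prompts(prompts: pd.DataFrame, events: pd.DataFrame) -> list[list[int]]:
    """Map each event report onto a scheduled prompt, day by day.

    Within a day, prompt i owns the window (t_{i-1}, t_i]; the first prompt
    additionally absorbs events from midnight, the last prompt events up to
    the end of its calendar day.  Events on a day with no prompts are
    dropped with a warning.
    """
    assignment: list[list[int]] = [[] for _ in range(len(prompts))]
    if events is None or not len(events):
        return assignment
    ts = pd.to_datetime(prompts["timestamp"])
    dates = ts.dt.date.to_numpy()
    for e_pos, (_, ev) in enumerate(events.iterrows()):
        ev_ts = pd.Timestamp(ev["timestamp"])
        day_mask = dates == ev_ts.date()
        idx = np.flatnonzero(day_mask)
        if not len(idx):
            warnings.warn("event report on a day with no scheduled prompts dropped", stacklevel=2)
            continue
        day_times = ts.iloc[idx].to_numpy()
        pos = int(np.searchsorted(day_times, np.datetime64(ev_ts), side="left"))
        pos = min(pos, len(idx) - 1)  # after the last prompt -> last prompt
        assignment[idx[pos]].append(e_pos)
    return assignment


def insert_day_padding(records: pd.DataFrame) -> pd.DataFrame:
    """Insert one all-missing row after the last prompt of every day.

    The padding row keeps only ``day`` (for bookkeeping) and an
    ``is_padding`` flag; all measured columns are missing.  Input must be
    sorted by timestamp.
    """
    if not len(records):
        out = records.copy()
        out["is_padding"] = pd.Series(dtype=bool)
        return out
    ts = pd.to_datetime(records["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("prompt records must be sorted by timestamp")
    out_blocks = []
    dates = ts.dt.date
    for _, block in records.groupby(dates, sort=True):
        block = block.copy()
        block["is_padding"] = False
        pad_values = {}
        for c in records.columns:
            if pd.api.types.is_datetime64_any_dtype(records[c]):
                pad_values[c] = pd.Series([pd.NaT], dtype=records[c].dtype)
            elif pd.api.types.is_object_dtype(records[c]):
                pad_values[c] = pd.Series([None], dtype=object)
            else:
                pad_values[c] = pd.Series([np.nan], dtype=float)
        pad = pd.DataFrame(pad_values)
        pad["day"] = block["day"].iloc[-1] if "day" in block.columns else np.nan
        pad["is_padding"] = True
        out_blocks.extend([block, pad])
    out = pd.concat(out_blocks, ignore_index=True)
    out["is_padding"] = out["is_padding"].astype(bool)
    return out


def shift_criterion(binge: pd.Series, is_padding: pd.Series) -> pd.Series:
    """Shift the binge indicator one prompt back in time.

    y at row i is the binge indicator at row i+1; missing where row i+1 is
    a padding row or absent, so no prediction spans a day boundary, and on
    padding rows themselves.
    """
    binge = pd.Series(np.asarray(binge, dtype=float))
    pad = np.asarray(is_padding, dtype=bool)
    y = binge.shift(-1)
    next_is_pad = np.roll(pad, -1)
    next_is_pad[-1] = True  # no next row
    y[next_is_pad] = np.nan
    y[pad] = np.nan
    return y


def cyclical_features(cumulative_hours: float, period: float) -> tuple[float, float]:
    """sin/cos pair of a cycle of the given period over cumulative hours."""
    if period <= 0:
        raise ValueError("period must be positive")
    angle = 2 * np.pi / period * cumulative_hours
    return float(np.sin(angle)), float(np.cos(angle))


def time_of_day_dummies(slot_index: int, n_slots: int = 6) -> np.ndarray:
    """One-hot indicators for the scheduled slot (1-based)."""
    if not 1 <= slot_index <= n_slots:
        raise ValueError(f"slot_index must lie in 1..{n_slots}, got {slot_index}")
    out = np.zeros(n_slots)
    out[slot_index - 1] = 1.0
    return out


def build_predictor_matrix(dataset: ParticipantDataset) -> pd.DataFrame:
    """Assemble the per-participant predictor matrix.

    Returns a frame with meta columns (timestamp, day, slot, cum_hours,
    answered, is_padding), the 44 canonical predictors, and the shifted
    criterion ``y_next``.  Cumulative hours come from the scheduled prompt
    grid, not actual response times.
    """
    prompts = dataset.prompts.sort_values("timestamp", kind="stable").reset_index(drop=True)
    if prompts.columns.duplicated().any():
        raise ValueError("duplicate column names in prompt records")
    ts = pd.to_datetime(prompts["timestamp"])
    cum_hours = (ts - ts.iloc[0]).dt.total_seconds() / 3600.0

    window_events = assign_events_to_prompts(prompts, dataset.events)
    binge = np.array(
        [
            derive_binge_outcome(
                prompts["meal_type"].iloc[i],
                bool(prompts["answered"].iloc[i]),
                dataset.events.iloc[window_events[i]] if window_events[i] else None,
            )
            for i in range(len(prompts))
        ]
    )

    base = prompts[["timestamp", "day", "slot"]].copy()
    base["cum_hours"] = cum_hours
    base["answered"] = prompts["answered"].astype(bool)
    for name in ITEM_NAMES:
        base[name] = prompts[name].astype(float) if name in prompts else np.nan
    base[AR_PREDICTOR] = binge
    for period in CYCLE_PERIODS:
        angle = 2 * np.pi / period * cum_hours
        base[f"sin_{int(period)}h"] = np.sin(angle)
        base[f"cos_{int(period)}h"] = np.cos(angle)
    dummies = np.stack([time_of_day_dummies(int(s), dataset.prompts_per_day) for s in prompts["slot"]])
    for j, name in enumerate(DUMMY_PREDICTORS[: dataset.prompts_per_day]):
        base[name] = dummies[:, j]
    for name in DUMMY_PREDICTORS[dataset.prompts_per_day :]:
        base[name] = 0.0

    padded = insert_day_padding(base)
    padded["answered"] = padded["answered"].fillna(False).astype(bool)
    padded[CRITERION] = shift_criterion(padded[AR_PREDICTOR], padded["is_padding"])

    cols = META_COLUMNS + PREDICTOR_NAMES + [CRITERION]
    return padded[cols]


# ---------------------------------------------------------------------------
# I/O: same long-format CSV schema as the simulator writes (and as a real
# app export would use)

def load_participants(
    prompts_csv: str | Path, events_csv: str | Path
) -> list[ParticipantDataset]:
    """Read per-participant datasets from long-format prompt/event CSVs."""
    prompts = pd.read_csv(prompts_csv, parse_dates=["timestamp"], dtype={"participant_id": str})
    events = pd.read_csv(events_csv, parse_dates=["timestamp"], dtype={"participant_id": str})
    for col in ("excessive_amount", "loss_of_control"):
        if col in events.columns:
            events[col] = events[col].map(lambda v: _as_bool(v))
    datasets = []
    for pid, block in prompts.groupby("participant_id", sort=True):
        block = block.drop(columns="participant_id").reset_index(drop=True)
        ev = (
            events[events["participant_id"] == pid]
            .drop(columns="participant_id")
            .reset_index(drop=True)
        )
        ppd = int(block["slot"].max())
        interval = 2.5
        same_day = block[block["day"] == block["day"].iloc[0]]
        if len(same_day) > 1:
            deltas = pd.to_datetime(same_day["timestamp"]).diff().dropna()
            interval = float(deltas.dt.total_seconds().iloc[0] / 3600.0)
        datasets.append(
            ParticipantDataset(
                participant_id=str(pid),
                prompts=block,
                events=ev,
                prompts_per_day=ppd,
                prompt_interval=interval,
            )
        )
    return datasets


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")


def read_matrix(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path, parse_dates=["timestamp"])
    out["answered"] = out["answered"].astype(bool)
    out["is_padding"] = out["is_padding"].astype(bool)
    return out
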