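"""Synthetic ecological momentary assessment (EMA) data with known ground truth.

Emulates a signal-contingent EMA protocol for binge-eating research: 6
prompts/day at 2.5 h intervals for 14 days (84 scheduled prompts), each
prompt carrying 31 antecedent items (slider and binary context items), a
meal-type response, and a compliance indicator, plus self-initiated
event-contingent overeating reports.  The binge process is a logistic
model on the previous prompt's standardized item states, time-of-day
terms, and the previous binge (autoregression), so every downstream
stage can be validated against a known predictor structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

#: canonical antecedent item names; the first 27 are 0-100 sliders, the
#: last 4 are binary context items (coded 0/1)
ITEM_NAMES: list[str] = [f"item_{i:02d}" for i in range(1, 32)]
SLIDER_ITEMS: list[str] = ITEM_NAMES[:27]
BINARY_ITEMS: list[str] = ITEM_NAMES[27:]

MEAL_TYPES = ("main meal", "snack", "binge", "none")

#: names for time-derived ground-truth drivers, matching the predictor
#: matrix columns built downstream
AR_NAME = "binge_now"
CYCLE_SIN24 = "sin_24h"
CYCLE_COS24 = "cos_24h"


class ConfigurationError(ValueError):
    """Raised when a TruthConfig violates its declared invariants."""


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth configuration for one simulated participant.

    The binge indicator at prompt t is drawn Bernoulli(expit(eta_t)) with

        eta_t = beta0 + cycle + slot
                + sum_j effect_j * z_j(t-1) + ar_effect * binge(t-1)

    where z_j is the standardized item state at the previous prompt of the
    same day (the antecedent terms vanish at the first prompt of a day).
    Item trajectories follow a bounded AR(1): sliders are clipped to
    [0, 100], binary context items threshold the same latent process.
    """

    n_days: int = 14
    prompts_per_day: int = 6
    prompt_interval: float = 2.5  # hours between prompts
    first_prompt_clock: float = 8.0  # hour of day of the first prompt
    beta0: float = float(logit(0.125))
    item_effects: dict[str, float] = field(default_factory=dict)
    cycle_amplitude: float = 0.0  # amplitude of a 24 h sinusoid on the logit
    cycle_phase: float = 0.0  # radians
    slot_effects: dict[int, float] = field(default_factory=dict)
    ar_effect: float = 0.0
    item_ar: float = 0.5  # AR(1) coefficient shared by all items
    item_mean: float = 40.0
    item_noise_sd: float = 15.0
    missing_rate: float = 0.2  # P(a scheduled prompt is unanswered), MCAR
    event_report_rate: float = 0.6  # P(a binge also triggers an event report)
    nonqualifying_event_rate: float = 0.05  # spurious event reports / prompt
    start_date: str = "2025-03-02"
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 1 or self.prompts_per_day < 1:
            raise ConfigurationError("n_days and prompts_per_day must be >= 1")
        if self.prompt_interval <= 0:
            raise ConfigurationError("prompt_interval must be positive")
        last_clock = self.first_prompt_clock + (self.prompts_per_day - 1) * self.prompt_interval
        if not (0 <= self.first_prompt_clock and last_clock < 24):
            raise ConfigurationError("prompt schedule must fit within one calendar day")
        for name, p in (
            ("missing_rate", self.missing_rate),
            ("event_report_rate", self.event_report_rate),
            ("nonqualifying_event_rate", self.nonqualifying_event_rate),
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        unknown = set(self.item_effects) - set(ITEM_NAMES)
        if unknown:
            raise ConfigurationError(f"item_effects refer to unknown items: {sorted(unknown)}")
        if not -1 < self.item_ar < 1:
            raise ConfigurationError("item_ar must lie in (-1, 1)")
        if self.item_noise_sd <= 0:
            raise ConfigurationError("item_noise_sd must be positive")
        bad_slots = [s for s in self.slot_effects if not 1 <= s <= self.prompts_per_day]
        if bad_slots:
            raise ConfigurationError(f"slot_effects refer to invalid slots: {bad_slots}")

    @property
    def n_prompts(self) -> int:
        return self.n_days * self.prompts_per_day

    def true_driver_names(self) -> list[str]:
        """Predictor-matrix column names with nonzero generative effects."""
        from .preprocess import DUMMY_PREDICTORS  # local import avoids a cycle

        names = [n for n, e in self.item_effects.items() if e != 0]
        if self.ar_effect != 0:
            names.append(AR_NAME)
        if self.cycle_amplitude != 0:
            names.extend([CYCLE_SIN24, CYCLE_COS24])
        names.extend(DUMMY_PREDICTORS[s - 1] for s, e in sorted(self.slot_effects.items()) if e != 0)
        return names


@dataclass
class ParticipantDataset:
    """One participant's raw EMA export.

    prompts: one row per scheduled prompt (timestamp, day, slot, items,
    meal_type, answered); unanswered prompts keep their timestamp but have
    missing items and meal_type.  events: event-contingent reports with
    excessive_amount / loss_of_control flags.
    """

    participant_id: str
    prompts: pd.DataFrame
    events: pd.DataFrame
    prompts_per_day: int = 6
    prompt_interval: float = 2.5


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    true_driver_names: list[str]
    realized_binge_count: int
    realized_compliance: float
    mean_event_probability: float
    binge_series: list[int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _schedule(config: TruthConfig) -> pd.DataFrame:
    t0 = datetime.fromisoformat(config.start_date)
    rows = []
    for d in range(config.n_days):
        for s in range(1, config.prompts_per_day + 1):
            clock = config.first_prompt_clock + (s - 1) * config.prompt_interval
            rows.append(
                {
                    "timestamp": t0 + timedelta(days=d, hours=clock),
                    "day": d + 1,
                    "slot": s,
                }
            )
    return pd.DataFrame(rows)


def _item_paths(config: TruthConfig, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent AR(1) paths for the 31 items and their standardized values.

    Returns (observed values, standardized latent drive).  Sliders are the
    latent clipped to [0, 100]; binary items threshold the latent at its
    mean.  Standardization uses the declared stationary moments so the
    generative effects are on a per-SD scale.
    """
    phi, mu, sd = config.item_ar, config.item_mean, config.item_noise_sd
    stat_sd = sd / np.sqrt(1 - phi**2)
    p = len(ITEM_NAMES)
    latent = np.empty((n, p))
    latent[0] = mu + rng.normal(0.0, stat_sd, size=p)
    noise = rng.normal(0.0, sd, size=(n - 1, p)) if n > 1 else np.empty((0, p))
    for t in range(1, n):
        latent[t] = mu + phi * (latent[t - 1] - mu) + noise[t - 1]
    observed = latent.copy()
    n_slider = len(SLIDER_ITEMS)
    observed[:, :n_slider] = np.clip(observed[:, :n_slider], 0.0, 100.0)
    observed[:, n_slider:] = (latent[:, n_slider:] > mu).astype(float)
    z = np.empty_like(observed)
    z[:, :n_slider] = (observed[:, :n_slider] - mu) / stat_sd
    z[:, n_slider:] = (observed[:, n_slider:] - 0.5) / 0.5
    return observed, z


def generate_participant(
    config: TruthConfig, participant_id: str = "01"
) -> tuple[ParticipantDataset, GroundTruth]:
    """Simulate one participant under ``config``.

    Deterministic given ``config.seed``.  Unanswered prompts (MCAR at the
    whole-prompt level) keep their timestamp; their binge status is only
    recoverable downstream through an event-contingent report.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sched = _schedule(config)
    n = len(sched)
    items, z = _item_paths(config, n, rng)

    cum_hours = (sched["timestamp"] - sched["timestamp"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    effect_vec = np.array([config.item_effects.get(name, 0.0) for name in ITEM_NAMES])
    drive = z @ effect_vec  # antecedent contribution of each prompt's state

    day = sched["day"].to_numpy()
    slot = sched["slot"].to_numpy()
    time_term = config.cycle_amplitude * np.sin(
        2 * np.pi / 24.0 * cum_hours + config.cycle_phase
    ) + np.array([config.slot_effects.get(int(s), 0.0) for s in slot])

    binge = np.zeros(n, dtype=int)
    prob = np.empty(n)
    u = rng.random(n)
    for t in range(n):
        eta = config.beta0 + time_term[t]
        if t > 0 and day[t] == day[t - 1]:
            eta += drive[t - 1] + config.ar_effect * binge[t - 1]
        prob[t] = expit(eta)
        binge[t] = int(u[t] < prob[t])

    answered = rng.random(n) >= config.missing_rate

    meal_type = np.full(n, None, dtype=object)
    meal_draw = rng.choice(["none", "main meal", "snack"], size=n, p=[0.4, 0.3, 0.3])
    for t in range(n):
        if answered[t]:
            meal_type[t] = "binge" if binge[t] else meal_draw[t]

    prompts = sched.copy()
    item_block = pd.DataFrame(items, columns=ITEM_NAMES)
    item_block[~answered] = np.nan
    prompts = pd.concat([prompts, item_block], axis=1)
    prompts["meal_type"] = meal_type
    prompts["answered"] = answered

    # event-contingent reports: a thinned subset of binges, timestamped in
    # the inter-prompt window preceding the prompt; plus occasional
    # non-qualifying reports (excessive amount without loss of control)
    events = []
    report_binge = rng.random(n) < config.event_report_rate
    report_spurious = rng.random(n) < config.nonqualifying_event_rate
    offsets = rng.uniform(0.0, config.prompt_interval, size=(n, 2))
    for t in range(n):
        ts = prompts["timestamp"].iloc[t]
        if binge[t] and report_binge[t]:
            events.append(
                {
                    "timestamp": ts - timedelta(hours=float(offsets[t, 0])),
                    "excessive_amount": True,
                    "loss_of_control": True,
                }
            )
        if report_spurious[t] and not binge[t]:
            events.append(
                {
                    "timestamp": ts - timedelta(hours=float(offsets[t, 1])),
                    "excessive_amount": True,
                    "loss_of_control": False,
                }
            )
    events_df = pd.DataFrame(events, columns=["timestamp", "excessive_amount", "loss_of_control"])
    if len(events_df):
        events_df = events_df.sort_values("timestamp", kind="stable").reset_index(drop=True)

    dataset = ParticipantDataset(
        participant_id=participant_id,
        prompts=prompts,
        events=events_df,
        prompts_per_day=config.prompts_per_day,
        prompt_interval=config.prompt_interval,
    )
    truth = GroundTruth(
        true_driver_names=config.true_driver_names(),
        realized_binge_count=int(binge.sum()),
        realized_compliance=float(answered.mean()),
        mean_event_probability=float(prob.mean()),
        binge_series=[int(b) for b in binge],
    )
    return dataset, truth


def generate_cohort(
    configs: list[TruthConfig], master_seed: int | None = None
) -> list[tuple[ParticipantDataset, GroundTruth]]:
    """Simulate independent participants.

    If ``master_seed`` is given, per-participant seeds are derived from it
    deterministically (overriding each config's own seed); otherwise each
    config's seed is used as-is.
    """
    if master_seed is not None:
        child = np.random.SeedSequence(master_seed).generate_state(max(len(configs), 1))
        configs = [
            dataclasses.replace(c, seed=int(child[i]) % 2**31) for i, c in enumerate(configs)
        ]
    return [
        generate_participant(c, participant_id=f"{i + 1:02d}") for i, c in enumerate(configs)
    ]


# ---------------------------------------------------------------------------
# on-disk representation (long-format CSV + ground-truth JSON)

def write_cohort(
    cohort: list[tuple[ParticipantDataset, GroundTruth]], out_dir: str | Path
) -> dict[str, Path]:
    """Write prompts.csv, events.csv and ground_truth.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prompt_frames, event_frames, truths = [], [], {}
    for dataset, truth in cohort:
        p = dataset.prompts.copy()
        p.insert(0, "participant_id", dataset.participant_id)
        prompt_frames.append(p)
        e = dataset.events.copy()
        e.insert(0, "participant_id", dataset.participant_id)
        event_frames.append(e)
        truths[dataset.participant_id] = truth.to_dict()
    prompts = pd.concat(prompt_frames, ignore_index=True)
    events = pd.concat(event_frames, ignore_index=True)
    events["excessive_amount"] = events["excessive_amount"].map({True: "yes", False: "no"})
    events["loss_of_control"] = events["loss_of_control"].map({True: "yes", False: "no"})
    paths = {
        "prompts": out / "prompts.csv",
        "events": out / "events.csv",
        "ground_truth": out / "ground_truth.json",
    }
    prompts.to_csv(paths["prompts"], index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")
    events.to_csv(paths["events"], index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")
    paths["ground_truth"].write_text(json.dumps(truths, indent=2))
    return paths
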