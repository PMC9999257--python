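"""Cohort-level reporting: per-participant table, aggregate statistics,
and the predictor-selection matrix, plus the end-to-end pipeline runner.

Aggregates use the arithmetic mean and sample SD (n-1) across
participants; the "mean 95% CI" convention averages the lower and upper
bootstrap bounds separately.  The selection matrix has one row per
participant and one canonical predictor column order; a cell holds the
signed derivation correlation of a selected predictor and can carry an
unadjusted two-tailed p-value star annotation (.05/.01/.001) from the
t approximation for a Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import synthetic_ema
from .biscuit import biscuit_select
from .evaluate import ParticipantResult, evaluate_participant
from .preprocess import PREDICTOR_NAMES, build_predictor_matrix, load_participants, write_matrix
from .synthetic_ema import SLIDER_ITEMS, TruthConfig, generate_cohort, write_cohort

logger = logging.getLogger("biscuit_ema")

#: metrics aggregated across participants
METRICS = (
    "auc",
    "ci_lower",
    "ci_upper",
    "sensitivity",
    "specificity",
    "r_d_mean",
    "r_cv_mean",
    "n_predictors",
)


@dataclass
class CohortSummary:
    """Cross-participant mean and sample SD per metric."""

    means: dict[str, float]
    sds: dict[str, float]  # NaN when n = 1 (sample SD undefined)
    n_participants: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSummary":
        return cls(**json.loads(Path(path).read_text()))


def aggregate_results(results: list[ParticipantResult]) -> CohortSummary:
    """Mean and sample SD of each metric over participants with defined values."""
    if not results:
        raise ValueError("cannot aggregate an empty result list")
    means, sds = {}, {}
    for metric in METRICS:
        vals = np.array(
            [getattr(r, metric) if metric != "n_predictors" else r.n_predictors for r in results],
            dtype=float,
        )
        vals = np.round(vals[np.isfinite(vals)], 6)  # 6-dp working precision
        if not len(vals):
            means[metric] = float("nan")
            sds[metric] = float("nan")
            continue
        means[metric] = round(float(vals.mean()), 6)
        sds[metric] = round(float(vals.std(ddof=1)), 6) if len(vals) > 1 else float("nan")
    return CohortSummary(means=means, sds=sds, n_participants=len(results))


def _p_stars(r: float, n: int) -> str:
    if not np.isfinite(r) or n < 3 or abs(r) >= 1:
        return ""
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def selection_matrix(
    results: list[ParticipantResult], annotate: bool = False
) -> pd.DataFrame:
    """Participants x predictors table of signed selection correlations.

    Columns follow the canonical predictor order, restricted to predictors
    selected by at least one participant.  With ``annotate=True`` cells are
    strings carrying unadjusted p-value stars.
    """
    if not results:
        raise ValueError("cannot build a selection matrix from an empty result list")
    selected_any = [
        p for p in PREDICTOR_NAMES if any(p in r.selected_predictors for r in results)
    ]
    extra = sorted(
        {p for r in results for p in r.selected_predictors} - set(selected_any)
    )
    columns = selected_any + extra
    table = pd.DataFrame(index=[r.participant_id for r in results], columns=columns, dtype=object)
    table.index.name = "participant_id"
    for r in results:
        for name, corr in r.selected_predictors.items():
            if annotate:
                table.loc[r.participant_id, name] = f"{corr:.2f}{_p_stars(corr, r.n_obs)}"
            else:
                table.loc[r.participant_id, name] = corr
    if not annotate:
        table = table.astype(float)
    return table


def results_table(results: list[ParticipantResult]) -> pd.DataFrame:
    """Per-participant metrics table (one row per participant)."""
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        d["n_predictors"] = r.n_predictors
        d.pop("selected_predictors")
        rows.append(d)
    return pd.DataFrame(rows).round(6)


# ---------------------------------------------------------------------------
# pipeline

DEFAULT_PIPELINE_CONFIG: dict = {
    "mode": "simulate",
    "n_participants": 13,
    "n_drivers": 3,
    "effect_magnitude": [0.8, 1.2],
    "n_folds": 10,
    "k_max": 20,
    "n_boot": 2000,
    "stratify": True,
    "generator": {},
}


def _cohort_configs(config: dict, seed: int) -> list[TruthConfig]:
    """Per-participant generator configs with idiographic driver subsets.

    Each participant gets ``n_drivers`` distinct slider items as true
    drivers, with effect magnitudes drawn uniformly from
    ``effect_magnitude`` and random sign.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.get("effect_magnitude", [0.8, 1.2])
    n_drivers = int(config.get("n_drivers", 3))
    base = dict(config.get("generator") or {})
    configs = []
    for _ in range(int(config["n_participants"])):
        drivers = rng.choice(len(SLIDER_ITEMS), size=n_drivers, replace=False)
        effects = {
            SLIDER_ITEMS[j]: float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
            for j in drivers
        }
        configs.append(TruthConfig(item_effects=effects, **base))
    return configs


def run_pipeline(
    config: dict | str | Path | None, out_dir: str | Path, seed: int = 0
) -> tuple[list[ParticipantResult], CohortSummary]:
    """simulate/ingest -> preprocess -> fit -> evaluate -> report.

    Writes table1.csv, summary.json, selection_matrix.csv, per-participant
    matrices and scales, and run_log.json.  Participants whose selection
    or evaluation fails (e.g. too few binges) are logged and excluded from
    aggregation.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = {**DEFAULT_PIPELINE_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg["mode"] == "simulate":
        if int(cfg["n_participants"]) < 1:
            raise ValueError("n_participants must be >= 1")
        configs = _cohort_configs(cfg, seed)
        cohort = generate_cohort(configs, master_seed=seed)
        write_cohort(cohort, out / "data")
        datasets = [d for d, _ in cohort]
        truths = {d.participant_id: t for d, t in cohort}
    elif cfg["mode"] == "ingest":
        datasets = load_participants(cfg["prompts_csv"], cfg["events_csv"])
        truths = {}
    else:
        raise ValueError(f"unknown pipeline mode: {cfg['mode']!r}")
    if not datasets:
        raise ValueError("no participants to process")

    eval_seeds = np.random.SeedSequence(seed).generate_state(len(datasets) + 1)[1:]
    results, skipped = [], []
    for i, dataset in enumerate(datasets):
        pid = dataset.participant_id
        try:
            matrix = build_predictor_matrix(dataset)
            write_matrix(matrix, out / f"matrix_{pid}.csv")
            scale = biscuit_select(
                matrix,
                n_folds=int(cfg["n_folds"]),
                k_grid=range(1, int(cfg["k_max"]) + 1),
                seed=int(eval_seeds[i]) % 2**31,
                stratify=bool(cfg["stratify"]),
            )
            scale.to_json(out / f"scale_{pid}.json")
            result = evaluate_participant(
                matrix,
                scale,
                participant_id=pid,
                n_boot=int(cfg["n_boot"]),
                seed=int(eval_seeds[i]) % 2**31,
            )
            result.to_json(out / f"result_{pid}.json")
            results.append(result)
        except ValueError as err:
            logger.warning("participant %s excluded: %s", pid, err)
            skipped.append({"participant_id": pid, "reason": str(err)})
    if not results:
        raise ValueError("every participant failed selection or evaluation")

    summary = aggregate_results(results)
    results_table(results).to_csv(out / "table1.csv", index=False)
    summary.to_json(out / "summary.json")
    selection_matrix(results, annotate=False).to_csv(out / "selection_matrix.csv")
    selection_matrix(results, annotate=True).to_csv(out / "selection_matrix_annotated.csv")
    log = {
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "generator"} | {"generator": cfg["generator"]},
        "skipped": skipped,
        "ground_truth_drivers": {pid: t.true_driver_names for pid, t in truths.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return results, summary
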