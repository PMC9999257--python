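"""Prediction-accuracy metrics for a fitted idiographic scale.

Scores every usable prompt with the unit-weighted scale and computes the
standard discrimination summary for a binary criterion: empirical AUC
(probability a randomly chosen binge prompt outscores a non-binge prompt,
ties counting half), a stratified percentile bootstrap 95% CI, and the
Youden-optimal cutoff with its sensitivity and specificity.  Sensitivity
and specificity are in-sample properties of the full-sample cutoff.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .biscuit import SelectedScale, score_matrix, summarize_reliability
from .preprocess import AR_PREDICTOR, CRITERION


def _clean(scores, y) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(scores) & np.isfinite(y)
    return scores[mask], y[mask]


def auc(scores, y) -> float:
    """Empirical AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed with midranks (equivalent to exhaustive pair counting).
    Raises if either class is absent.
    """
    scores, y = _clean(scores, y)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_ci(
    scores, y, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC.

    Resamples positives and negatives separately with replacement (so
    every resample keeps both classes); resamples with an undefined AUC
    are skipped, and more than 50% skipped is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    scores, y = _clean(scores, y)
    auc(scores, y)  # validate both classes present
    rng = np.random.default_rng(seed)
    pos_scores = scores[y == 1]
    neg_scores = scores[y == 0]
    stats = []
    for _ in range(n_boot):
        ps = rng.choice(pos_scores, size=len(pos_scores), replace=True)
        ns = rng.choice(neg_scores, size=len(neg_scores), replace=True)
        try:
            stats.append(
                auc(np.concatenate([ps, ns]), np.concatenate([np.ones(len(ps)), np.zeros(len(ns))]))
            )
        except ValueError:
            continue
    if len(stats) < n_boot / 2:
        raise ValueError("more than half of bootstrap resamples were degenerate")
    alpha = (1 - level) / 2
    lower, upper = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lower), float(upper)


def optimal_cutoff(scores, y) -> tuple[float, float, float]:
    """Youden-optimal threshold: (cutoff, sensitivity, specificity).

    Scans midpoints between adjacent distinct scores plus +/-inf, with
    predicted-positive meaning score >= cutoff.  Ties in Youden J resolve
    to the smallest cutoff (favoring sensitivity: for a just-in-time
    intervention a missed binge is costlier than a false alarm).
    """
    scores, y = _clean(scores, y)
    auc(scores, y)  # validate
    pos = scores[y == 1]
    neg = scores[y == 0]
    distinct = np.unique(scores)
    cutoffs = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
    best = None
    for c in cutoffs:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        j = sens + spec
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    return best[1], best[2], best[3]


@dataclass
class ParticipantResult:
    """One participant's row of the per-participant results table."""

    participant_id: str
    auc: float
    ci_lower: float
    ci_upper: float
    sensitivity: float
    specificity: float
    cutoff: float
    r_d_mean: float
    r_d_sd: float
    r_cv_mean: float
    r_cv_sd: float
    selected_predictors: dict[str, float] = field(default_factory=dict)
    n_prompts_answered: int = 0
    n_binges: int = 0
    n_obs: int = 0

    @property
    def n_predictors(self) -> int:
        return len(self.selected_predictors)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "ParticipantResult":
        return cls(**json.loads(Path(path).read_text()))


def evaluate_participant(
    M: pd.DataFrame,
    scale: SelectedScale,
    participant_id: str = "01",
    n_boot: int = 2000,
    seed: int = 0,
) -> ParticipantResult:
    """Fill a ParticipantResult from a matrix and its fitted scale."""
    rows = M
    if "is_padding" in M.columns:
        rows = rows[~rows["is_padding"].astype(bool)]
    usable = rows[pd.notna(rows[CRITERION])]
    scores = score_matrix(usable, scale)
    y = usable[CRITERION].to_numpy(dtype=float)

    a = auc(scores, y)
    lo, hi = bootstrap_ci(scores, y, n_boot=n_boot, seed=seed)
    cut, sens, spec = optimal_cutoff(scores, y)
    if scale.diagnostics is not None:
        rd_m, rd_s, rcv_m, rcv_s = summarize_reliability(scale.diagnostics)
    else:
        rd_m = rd_s = rcv_m = rcv_s = float("nan")

    answered = int(rows["answered"].sum()) if "answered" in rows.columns else len(rows)
    binges = rows[AR_PREDICTOR].to_numpy(dtype=float) if AR_PREDICTOR in rows.columns else np.array([])
    n_binges = int(np.nansum(binges)) if len(binges) else 0

    return ParticipantResult(
        participant_id=participant_id,
        auc=a,
        ci_lower=lo,
        ci_upper=hi,
        sensitivity=sens,
        specificity=spec,
        cutoff=cut,
        r_d_mean=rd_m,
        r_d_sd=rd_s,
        r_cv_mean=rcv_m,
        r_cv_sd=rcv_s,
        selected_predictors=dict(scale.item_corrs),
        n_prompts_answered=answered,
        n_binges=n_binges,
        n_obs=len(y),
    )
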