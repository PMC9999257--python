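"""BISCUIT: Best Items Scale that is Cross-validated, Unit-weighted,
Informative and Transparent.

Given a predictor matrix and a binary criterion, the algorithm (1) ranks
predictors by the absolute pairwise Pearson correlation (point-biserial
for a binary criterion) with the criterion, (2) forms candidate
unit-weighted scales from the top-k predictors for each k in a grid, with
each item keyed by the sign of its correlation, (3) estimates each
candidate's out-of-sample validity by k-fold cross-validation (the mean
correlation of the held-out scale score with the criterion), and
(4) retains the k with the highest cross-validated correlation, refit on
all rows.  Correlations use pairwise-complete observations and the scale
score prorates over observed items, so the method degrades gracefully
under the prompt-level missingness typical of high-burden EMA designs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import CRITERION, META_COLUMNS, PREDICTOR_NAMES


def pairwise_pearson(x, y, *, warn: bool = True) -> float:
    """Pearson correlation on pairwise-complete observations.

    Returns NaN (optionally with a warning) when fewer than 3 complete
    pairs exist or either series is constant on the joint support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        if warn:
            warnings.warn("fewer than 3 complete pairs; correlation undefined", stacklevel=2)
        return float("nan")
    xs, ys = x[mask], y[mask]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        if warn:
            warnings.warn("constant series on joint support; correlation undefined", stacklevel=2)
        return float("nan")
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def _nan_equal(a, b) -> bool:
    """Structural equality where NaN == NaN (for fold slots without positives)."""
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(_nan_equal(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(_nan_equal(x, y) for x, y in zip(a, b))
    if isinstance(a, float) and isinstance(b, float) and np.isnan(a) and np.isnan(b):
        return True
    return a == b


@dataclass
class SelectionDiagnostics:
    """Fold-level and grid-level bookkeeping from one BISCUIT run."""

    predictor_corrs: dict[str, float]  # full-data pairwise r with the criterion
    k_grid: list[int]
    mean_cv_by_k: dict[int, float]
    fold_derivation: list[float]  # per-fold training r of the chosen-k scale
    fold_validation: list[float]  # per-fold held-out r of the chosen-k scale
    n_folds: int

    def __eq__(self, other):
        if not isinstance(other, SelectionDiagnostics):
            return NotImplemented
        return _nan_equal(dataclasses.asdict(self), dataclasses.asdict(other))


@dataclass
class SelectedScale:
    """A fitted unit-weighted scale: signed keys plus standardization stats."""

    names: list[str]
    keys: list[int]  # +1 / -1, sign of the derivation correlation
    k: int
    item_corrs: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    n_obs: int
    diagnostics: SelectionDiagnostics | None = None

    def __eq__(self, other):
        if not isinstance(other, SelectedScale):
            return NotImplemented
        return _nan_equal(dataclasses.asdict(self), dataclasses.asdict(other))

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectedScale":
        payload = json.loads(Path(path).read_text())
        diag = payload.pop("diagnostics", None)
        if diag is not None:
            diag["mean_cv_by_k"] = {int(k): v for k, v in diag["mean_cv_by_k"].items()}
            diag = SelectionDiagnostics(**diag)
        return cls(diagnostics=diag, **payload)


def unit_weighted_score(row: Mapping[str, float], scale: SelectedScale) -> float:
    """Prorated unit-weighted score of one observation.

    Mean over the *observed* keyed items of key_j * z_j, standardizing with
    the scale's stored derivation mean/SD; NaN when every keyed item is
    missing.
    """
    total, count = 0.0, 0
    for name, key in zip(scale.names, scale.keys):
        v = row.get(name, np.nan) if hasattr(row, "get") else row[name]
        sd = scale.sds[name]
        if v is None or not np.isfinite(v) or sd == 0:
            continue
        total += key * (v - scale.means[name]) / sd
        count += 1
    return total / count if count else float("nan")


def _score_block(
    X: np.ndarray, order: np.ndarray, signs: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> np.ndarray:
    """Scores of every top-k scale at once.

    X is rows x predictors; order lists predictor columns by descending
    |r|.  Returns rows x len(order): column k-1 holds the prorated
    unit-weighted score of the top-k scale.
    """
    Z = (X[:, order] - means[order]) / sds[order]
    keyed = signs[order] * Z
    observed = np.isfinite(keyed)
    keyed = np.where(observed, keyed, 0.0)
    sums = np.cumsum(keyed, axis=1)
    counts = np.cumsum(observed, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def _corr_columns(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise-complete correlation of each column of S with y (quiet)."""
    return np.array([pairwise_pearson(S[:, j], y, warn=False) for j in range(S.shape[1])])


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator, stratify: bool
) -> list[np.ndarray]:
    """Deterministic (seeded) fold assignment over row positions.

    Stratified mode deals each class out round-robin after an in-class
    shuffle, so positives spread as evenly as the counts allow even when
    there are fewer positives than folds.
    """
    n = len(y)
    fold_of = np.empty(n, dtype=int)
    if stratify:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % n_folds
    else:
        perm = rng.permutation(n)
        fold_of[perm] = np.arange(n) % n_folds
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


def _rank_predictors(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(correlations, order of defined predictors by descending |r|).

    Ties in |r| break by canonical predictor index for determinism;
    predictors with undefined correlation are excluded from the order.
    """
    corrs = np.array([pairwise_pearson(X[:, j], y, warn=False) for j in range(X.shape[1])])
    defined = np.flatnonzero(np.isfinite(corrs))
    order = defined[np.lexsort((defined, -np.abs(corrs[defined])))]
    return corrs, order


def _run_folds(
    X: np.ndarray,
    y: np.ndarray,
    folds: list[np.ndarray],
    k_grid: Sequence[int],
    warn: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Derivation and validation correlations per (fold, k).

    Each fold ranks predictors on its training rows, builds the top-k
    unit-weighted scale with training standardization, and correlates the
    scale score with the criterion in-fold and held-out.
    """
    n_k = len(k_grid)
    r_train = np.full((len(folds), n_k), np.nan)
    r_val = np.full((len(folds), n_k), np.nan)
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        if len(val_idx) == 0 or len(train_idx) == 0:
            continue
        Xt, yt = X[train_idx], y[train_idx]
        corrs, order = _rank_predictors(Xt, yt)
        if not len(order):
            continue
        signs = np.where(corrs >= 0, 1.0, -1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            means = np.nanmean(Xt, axis=0)
            sds = np.nanstd(Xt, axis=0)
        sds[sds == 0] = np.nan  # constant in training: contributes nothing
        S_train = _score_block(Xt, order, signs, means, sds)
        S_val = _score_block(X[val_idx], order, signs, means, sds)
        rt = _corr_columns(S_train, yt)
        rv = _corr_columns(S_val, y[val_idx])
        if warn and np.all(np.isnan(rv)):
            warnings.warn(
                f"fold {f}: held-out correlation undefined (e.g. no positive cases)",
                stacklevel=3,
            )
        for j, k in enumerate(k_grid):
            if k <= len(order):
                r_train[f, j] = rt[k - 1]
                r_val[f, j] = rv[k - 1]
    return r_train, r_val


def biscuit_select(
    M: pd.DataFrame,
    n_folds: int = 10,
    k_grid: Sequence[int] | None = None,
    seed: int = 0,
    stratify: bool = True,
    predictors: Sequence[str] | None = None,
) -> SelectedScale:
    """Run BISCUIT on one participant's predictor matrix.

    ``M`` must carry the criterion column ``y_next``; padding rows and rows
    with a missing criterion are excluded up front.  ``k_grid`` defaults to
    1..min(20, #predictors).  Deterministic given ``seed``.
    """
    if predictors is None:
        predictors = [c for c in M.columns if c in PREDICTOR_NAMES]
        if not predictors:
            predictors = [c for c in M.columns if c not in META_COLUMNS + [CRITERION]]
    predictors = list(predictors)
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictor names")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")

    rows = M
    if "is_padding" in M.columns:
        rows = rows[~rows["is_padding"].astype(bool)]
    rows = rows[pd.notna(rows[CRITERION])]
    y = rows[CRITERION].to_numpy(dtype=float)
    X = rows[predictors].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 rows of each criterion class to select predictors")

    if k_grid is None:
        k_grid = range(1, min(20, len(predictors)) + 1)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid or k_grid[0] < 1:
        raise ValueError("k_grid values must be >= 1")

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng, stratify)
    r_train, r_val = _run_folds(X, y, folds, k_grid)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_cv = np.nanmean(r_val, axis=0)
    if np.all(np.isnan(mean_cv)):
        raise ValueError("cross-validated correlation undefined for every candidate k")
    best_j = int(np.nanargmax(mean_cv))  # ties resolve to the smallest k
    best_k = k_grid[best_j]

    # r_D / r_CV diagnostics come from a nested cross-validation: each
    # outer fold re-chooses k on its training rows only, so the held-out
    # correlation estimates the whole selection procedure without the
    # winner's-curse bias of reporting the maximizing k's own CV folds
    rd_folds = np.full((n_folds, 1), np.nan)
    rcv_folds = np.full((n_folds, 1), np.nan)
    outer = _stratified_folds(y, n_folds, rng, stratify)
    for f, val_idx in enumerate(outer):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        yt = y[train_idx]
        if len(np.unique(yt)) < 2:
            continue
        inner = _stratified_folds(yt, n_folds, rng, stratify)
        _, rv_inner = _run_folds(X[train_idx], yt, inner, k_grid, warn=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            inner_mean = np.nanmean(rv_inner, axis=0)
        if np.all(np.isnan(inner_mean)):
            # too few positives in this fold's training rows to re-choose
            # k (e.g. a 2-binge participant); fall back to the global k
            k_f = best_k
        else:
            k_f = k_grid[int(np.nanargmax(inner_mean))]
        rd_f, rcv_f = _run_folds(X, y, [val_idx], [k_f], warn=False)
        rd_folds[f, 0] = rd_f[0, 0]
        rcv_folds[f, 0] = rcv_f[0, 0]
    if np.all(np.isnan(rcv_folds)):
        warnings.warn("every outer fold's held-out correlation is undefined", stacklevel=2)

    # refit on all rows at the chosen k
    corrs, order = _rank_predictors(X, y)
    best_k = min(best_k, len(order))
    sel = order[:best_k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(X[:, sel], axis=0)
        sds = np.nanstd(X[:, sel], axis=0)

    diagnostics = SelectionDiagnostics(
        predictor_corrs={p: float(corrs[j]) for j, p in enumerate(predictors)},
        k_grid=list(k_grid),
        mean_cv_by_k={k: float(mean_cv[j]) for j, k in enumerate(k_grid)},
        fold_derivation=[float(v) for v in rd_folds[:, 0]],
        fold_validation=[float(v) for v in rcv_folds[:, 0]],
        n_folds=n_folds,
    )
    return SelectedScale(
        names=[predictors[j] for j in sel],
        keys=[1 if corrs[j] >= 0 else -1 for j in sel],
        k=best_k,
        item_corrs={predictors[j]: float(corrs[j]) for j in sel},
        means={predictors[j]: float(m) for j, m in zip(sel, means)},
        sds={predictors[j]: float(s) for j, s in zip(sel, sds)},
        n_obs=len(y),
        diagnostics=diagnostics,
    )


def score_matrix(M: pd.DataFrame, scale: SelectedScale) -> np.ndarray:
    """Vectorized unit-weighted scores for every row of a matrix."""
    X = M[scale.names].to_numpy(dtype=float)
    keys = np.array(scale.keys, dtype=float)
    means = np.array([scale.means[n] for n in scale.names])
    sds = np.array([scale.sds[n] for n in scale.names])
    sds = np.where(sds == 0, np.nan, sds)
    keyed = keys * (X - means) / sds
    observed = np.isfinite(keyed)
    sums = np.where(observed, keyed, 0.0).sum(axis=1)
    counts = observed.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def summarize_reliability(
    diagnostics: SelectionDiagnostics,
) -> tuple[float, float, float, float]:
    """(r_D mean, r_D SD, r_CV mean, r_CV SD) across folds.

    Sample SD (n-1); folds with undefined correlations are excluded; all
    folds undefined is an error.
    """
    rd = np.array(diagnostics.fold_derivation, dtype=float)
    rcv = np.array(diagnostics.fold_validation, dtype=float)
    rd = rd[np.isfinite(rd)]
    rcv = rcv[np.isfinite(rcv)]
    if not len(rd) or not len(rcv):
        raise ValueError("no fold with defined correlations")
    rd_sd = float(rd.std(ddof=1)) if len(rd) > 1 else float("nan")
    rcv_sd = float(rcv.std(ddof=1)) if len(rcv) > 1 else float("nan")
    return float(rd.mean()), rd_sd, float(rcv.mean()), rcv_sd
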