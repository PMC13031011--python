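"""Composite AF burden score and Youden-index cutoff selection.

The score is a weighted sum of min-max-normalized 5D features, so it lives
on [0, 1] and a printed cutoff is directly interpretable.  Weights integrate
three agreement ingredients per feature — |Pearson r|, R² and ICC (floored
at 0) — as their arithmetic mean, renormalized to sum to 1 (geometric-mean
and user-supplied modes are available).  The diagnostic cutoff against
clinical event labels maximizes Youden's J = sensitivity + specificity − 1
over all midpoint thresholds, classifying a subject positive when
score >= cutoff.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreModel",
    "YoudenResult",
    "normalize_features",
    "apply_normalization",
    "derive_weights",
    "composite_score",
    "youden_cutoff",
    "fit_score_model",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreModel:
    """Frozen normalization, weights and cutoff of a fitted burden score."""

    feature_names: list[str]
    normalization: dict[str, tuple[float, float]]  # feature -> (min, max)
    weights: dict[str, float]
    cutoff: float = math.nan
    cutoff_sens: float = math.nan
    cutoff_spec: float = math.nan
    youden_j: float = math.nan

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if self.weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        for name, (lo, hi) in self.normalization.items():
            if not lo < hi:
                raise ValueError(f"normalization min >= max for {name}")

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "normalization": {k: list(v) for k, v in self.normalization.items()},
            "weights": self.weights,
            "cutoff": self.cutoff,
            "cutoff_sens": self.cutoff_sens,
            "cutoff_spec": self.cutoff_spec,
            "youden_j": self.youden_j,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            normalization={k: tuple(v) for k, v in d["normalization"].items()},
            weights=d["weights"],
            cutoff=d["cutoff"],
            cutoff_sens=d["cutoff_sens"],
            cutoff_spec=d["cutoff_spec"],
            youden_j=d["youden_j"],
        )


def normalize_features(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Min-max normalize a cohort feature table to [0, 1] per feature.

    Features with zero variance or no observed values are dropped (logged);
    missing values are imputed as 0 *after* normalization.  Returns the
    normalized table and the per-feature (min, max) parameters.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 subjects to normalize")
    params: dict[str, tuple[float, float]] = {}
    cols = {}
    for name in table.columns:
        x = table[name].to_numpy(float)
        finite = np.isfinite(x)
        if not finite.any():
            logger.warning("dropping all-missing feature %s", name)
            continue
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
        if not lo < hi:
            logger.warning("dropping zero-variance feature %s", name)
            continue
        params[name] = (lo, hi)
        xn = (x - lo) / (hi - lo)
        xn[~finite] = 0.0
        cols[name] = xn
    return pd.DataFrame(cols, index=table.index), params


def apply_normalization(
    table: pd.DataFrame, params: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Apply stored min-max parameters to new data (values clipped to [0, 1])."""
    cols = {}
    for name, (lo, hi) in params.items():
        x = table[name].to_numpy(float)
        xn = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        xn[~np.isfinite(x)] = 0.0
        cols[name] = xn
    return pd.DataFrame(cols, index=table.index)


def derive_weights(
    stats: dict[str, dict[str, float]],
    mode: str = "mean",
    user_weights: dict[str, float] | None = None,
) -> dict[str, float]:
    """Integrate per-feature agreement statistics into score weights.

    ``stats`` maps feature -> {"r": Pearson r, "r2": R², "icc": ICC}.  The
    raw weight is mean(|r|, R², max(ICC, 0)) (or the geometric mean in
    ``mode="geometric"``); missing ingredients count as 0.  Raw weights are
    renormalized to sum to 1.
    """
    if mode == "user":
        if not user_weights:
            raise ValueError("user mode needs user_weights")
        total = sum(user_weights.values())
        if total <= 0:
            raise ValueError("user weights must have positive sum")
        return {k: v / total for k, v in user_weights.items()}
    raw: dict[str, float] = {}
    for feat, s in stats.items():
        parts = np.array([
            abs(s.get("r", 0.0) or 0.0),
            s.get("r2", 0.0) or 0.0,
            max(s.get("icc", 0.0) or 0.0, 0.0),
        ])
        parts = np.nan_to_num(parts)
        if mode == "geometric":
            raw[feat] = float(np.prod(parts) ** (1 / 3)) if (parts > 0).all() else 0.0
        elif mode == "mean":
            raw[feat] = float(parts.mean())
        else:
            raise ValueError(f"unknown weight mode {mode!r}")
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("degenerate weights: all agreement statistics are zero")
    return {k: v / total for k, v in raw.items()}


def composite_score(
    normalized: pd.DataFrame | pd.Series | np.ndarray,
    model: ScoreModel,
) -> np.ndarray:
    """Weighted sum of normalized features, clamped to [0, 1]."""
    names = list(model.weights)
    w = np.array([model.weights[k] for k in names])
    if isinstance(normalized, pd.DataFrame):
        missing = [k for k in names if k not in normalized.columns]
        if missing:
            raise ValueError(f"score features absent from table: {missing}")
        X = normalized[names].to_numpy(float)
    elif isinstance(normalized, pd.Series):
        X = normalized[names].to_numpy(float)[None, :]
    else:
        X = np.atleast_2d(np.asarray(normalized, float))
        if X.shape[1] != len(names):
            raise ValueError(
                f"vector has {X.shape[1]} entries, model has {len(names)} features"
            )
    return np.clip(X @ w, 0.0, 1.0)


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    sensitivity: float
    specificity: float
    j: float


def youden_cutoff(scores, event_flags) -> YoudenResult:
    """Cutoff maximizing Youden's J over all midpoint thresholds.

    Candidates are midpoints between consecutive sorted unique scores plus
    -inf/+inf sentinels; a subject is positive iff score >= cutoff; ties in
    J break toward the smallest cutoff.
    """
    s = np.asarray(scores, float)
    y = np.asarray(event_flags, bool)
    if s.shape != y.shape:
        raise ValueError("scores and event_flags must align")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden cutoff undefined with a single class")
    u = np.unique(s)
    cand = np.concatenate([[-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]])
    order = np.argsort(s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    # number of scores strictly below each candidate
    below = np.searchsorted(s_sorted, cand, side="left")
    fn = cum_pos[below]
    tn = below - fn
    sens = (n_pos - fn) / n_pos
    spec = tn / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first max = smallest cutoff (cand ascending)
    return YoudenResult(
        cutoff=float(cand[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        j=float(j[best]),
    )


def fit_score_model(
    features: pd.DataFrame,
    agreement_stats: dict[str, dict[str, float]],
    event_flags: pd.Series | np.ndarray | None = None,
    weight_mode: str = "mean",
) -> tuple[ScoreModel, np.ndarray]:
    """Normalize, weight, score a cohort and (optionally) pick the cutoff.

    Returns the fitted model plus the per-subject composite scores.  Only
    features that survive normalization *and* have agreement statistics
    enter the score.
    """
    normalized, params = normalize_features(features)
    usable = {
        k: v for k, v in agreement_stats.items() if k in normalized.columns
    }
    if not usable:
        raise ValueError("no feature has both variance and agreement statistics")
    weights = derive_weights(usable, mode=weight_mode)
    model = ScoreModel(
        feature_names=list(weights),
        normalization={k: params[k] for k in weights},
        weights=weights,
    )
    scores = composite_score(normalized, model)
    if event_flags is not None:
        y = np.asarray(event_flags, bool)
        if y.all() or not y.any():
            logger.warning("single-class event labels: cutoff left missing")
        else:
            res = youden_cutoff(scores, y)
            model.cutoff = res.cutoff
            model.cutoff_sens = res.sensitivity
            model.cutoff_spec = res.specificity
            model.youden_j = res.j
    return model, scores
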