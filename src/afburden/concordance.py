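"""Agreement and diagnostic statistics: index device vs reference.

Per-feature method agreement (MAE, Pearson/Spearman/Kendall battery, R² with
bootstrap CI, ICC(2,1) absolute agreement with F-based CI) and per-epoch
diagnostic performance (sensitivity/specificity/accuracy with Wilson score
CIs, ROC and precision-recall curves) between a wearable index device and a
reference Holter channel, plus the Kruskal-Wallis H test for comparing
feature distributions across clinical categories.

Conventions: all tests two-sided at alpha = 0.05; no multiple-testing
correction is applied (reports state this in their header).  Statistics
whose preconditions fail (zero variance, single class, too few pairs) are
*missing* (NaN), never 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from statsmodels.stats.proportion import proportion_confint

from .streams import AF, EpochStream

__all__ = [
    "PairedFeatureSeries",
    "mae",
    "correlation_battery",
    "r_squared",
    "icc_2way_absolute",
    "icc_band",
    "wilson_ci",
    "confusion_metrics",
    "roc_pr",
    "kruskal_wallis",
    "build_report",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class PairedFeatureSeries:
    """Per-subject (index pᵢ, reference gᵢ) pairs for one feature.

    Pairs where either side is missing are removed on construction.
    """

    feature_name: str
    p: np.ndarray
    g: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, float)
        g = np.asarray(self.g, float)
        if p.shape != g.shape:
            raise ValueError("p and g must have equal length")
        keep = np.isfinite(p) & np.isfinite(g)
        self.p, self.g = p[keep], g[keep]
        if self.subject_ids is not None:
            self.subject_ids = [s for s, k in zip(self.subject_ids, keep) if k]

    @property
    def n(self) -> int:
        return int(self.p.size)


def mae(series: PairedFeatureSeries) -> float:
    """Mean absolute error between index and reference values."""
    if series.n == 0:
        raise ValueError("MAE undefined for an empty series")
    return float(np.abs(series.p - series.g).mean())


def _degenerate(x: np.ndarray) -> bool:
    return np.ptp(x) == 0


def correlation_battery(series: PairedFeatureSeries) -> dict[str, float]:
    """Pearson r, Spearman rho (midranks) and Kendall tau-b with p-values.

    Zero variance in either series leaves all entries missing.
    """
    out = dict.fromkeys(
        ["pearson_r", "pearson_p", "spearman_rho", "spearman_p",
         "kendall_tau", "kendall_p"], math.nan,
    )
    p, g = series.p, series.g
    if series.n < 3 or _degenerate(p) or _degenerate(g):
        return out
    pr = sps.pearsonr(p, g)
    sr = sps.spearmanr(p, g)
    kt = sps.kendalltau(p, g, variant="b")
    out.update(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        kendall_tau=float(kt.statistic), kendall_p=float(kt.pvalue),
    )
    return out


def r_squared(
    series: PairedFeatureSeries, ci_bootstrap_n: int = 1000, seed: int = 0
) -> dict[str, float]:
    """R² of the reference on the index device (simple linear regression).

    The point estimate is the squared Pearson correlation; the 95% CI is a
    seeded percentile bootstrap over subjects.
    """
    out = dict.fromkeys(["r_squared", "r_squared_lo", "r_squared_hi"], math.nan)
    p, g = series.p, series.g
    n = series.n
    if n < 3 or _degenerate(p) or _degenerate(g):
        return out
    r2 = float(sps.pearsonr(p, g).statistic ** 2)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(ci_bootstrap_n):
        idx = rng.integers(0, n, n)
        pb, gb = p[idx], g[idx]
        if _degenerate(pb) or _degenerate(gb):
            continue
        boots.append(sps.pearsonr(pb, gb).statistic ** 2)
    if boots:
        lo, hi = np.percentile(boots, [100 * ALPHA / 2, 100 * (1 - ALPHA / 2)])
        out.update(r_squared_lo=float(lo), r_squared_hi=float(hi))
    out["r_squared"] = r2
    return out


def icc_band(icc: float) -> str:
    """Consistency band: >0.75 excellent, 0.50-0.75 moderate, <0.50 poor."""
    if not np.isfinite(icc):
        return "undefined"
    if icc > 0.75:
        return "excellent"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def icc_2way_absolute(matrix: np.ndarray, alpha: float = ALPHA) -> dict[str, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares of an n x k ratings matrix
    (subjects x raters):

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),

    with the McGraw-Wong F-based confidence interval.  Degenerate input
    (zero total variance) yields NaN throughout.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 raters")
    n, k = X.shape
    if n < 3:
        raise ValueError("need >= 3 subjects")
    out = dict.fromkeys(["icc", "icc_lo", "icc_hi"], math.nan)
    gm = X.mean()
    if np.allclose(X, gm):
        return out
    rm = X.mean(axis=1)
    cm = X.mean(axis=0)
    msr = k * ((rm - gm) ** 2).sum() / (n - 1)
    msc = n * ((cm - gm) ** 2).sum() / (k - 1)
    sse = ((X - rm[:, None] - cm[None, :] + gm) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return out
    icc = (msr - mse) / denom
    out["icc"] = float(icc)

    # McGraw & Wong F interval for ICC(A,1)
    if mse > 0 and icc < 1.0:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_obs = msr / mse
        fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
        fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (
            fl * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (fu * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * fu * msr
        )
        del f_obs
        out["icc_lo"] = float(min(lo, icc))
        out["icc_hi"] = float(max(hi, icc))
    return out


def wilson_ci(k: int, n: int, alpha: float = ALPHA) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, no continuity correction."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    # boundary cases are exactly 0/1 in the closed form; keep them exact
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return float(lo), float(hi)


def confusion_metrics(
    pred: EpochStream, truth: EpochStream
) -> dict[str, float | tuple[float, float]]:
    """Per-epoch sensitivity/specificity/accuracy with Wilson 95% CIs.

    Streams are joined on exact epoch timestamps; epochs invalid on either
    device are excluded pairwise.  A metric whose denominator class is
    absent is missing.
    """
    common, ip, it = np.intersect1d(pred.times, truth.times, return_indices=True)
    if common.size == 0:
        raise ValueError("streams share no epochs")
    keep = pred.valid_mask[ip] & truth.valid_mask[it]
    yp = pred.labels[ip][keep] == AF
    yt = truth.labels[it][keep] == AF
    n = int(keep.sum())
    out: dict[str, float | tuple[float, float]] = {"n_epochs": n}
    tp = int((yp & yt).sum())
    tn = int((~yp & ~yt).sum())
    npos, nneg = int(yt.sum()), int((~yt).sum())
    for name, k, m in (
        ("sensitivity", tp, npos),
        ("specificity", tn, nneg),
        ("accuracy", tp + tn, n),
    ):
        if m == 0:
            out[name] = math.nan
            out[f"{name}_ci"] = (math.nan, math.nan)
        else:
            out[name] = k / m
            out[f"{name}_ci"] = wilson_ci(k, m)
    return out


def roc_pr(
    scores: np.ndarray,
    truth: np.ndarray,
    ci_bootstrap_n: int = 1000,
    seed: int = 0,
) -> dict[str, object]:
    """ROC curve/AUC (trapezoid, with bootstrap CI) and PR curve/AP."""
    s = np.asarray(scores, float)
    y = np.asarray(truth, bool)
    if y.all() or not y.any():
        raise ValueError("ROC undefined with a single class")
    fpr, tpr, _ = roc_curve(y, s)
    roc_auc = float(auc(fpr, tpr))
    prec, rec, _ = precision_recall_curve(y, s)
    ap = float(average_precision_score(y, s))
    rng = np.random.default_rng(seed)
    boots = []
    n = s.size
    for _ in range(ci_bootstrap_n):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            continue
        fb, tb, _ = roc_curve(yb, s[idx])
        boots.append(auc(fb, tb))
    ci = (
        tuple(np.percentile(boots, [100 * ALPHA / 2, 100 * (1 - ALPHA / 2)]))
        if boots
        else (math.nan, math.nan)
    )
    return {
        "roc_auc": roc_auc,
        "roc_auc_ci": (float(ci[0]), float(ci[1])),
        "roc_curve": (fpr, tpr),
        "pr_curve": (prec, rec),
        "pr_auc": ap,
    }


def kruskal_wallis(*groups) -> dict[str, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) with chi-square p-value.

    All observations identical is taken as H = 0, p = 1 (the tie correction
    degenerates).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if pooled.size < 3:
        raise ValueError("need total n >= 3")
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return {"H": 0.0, "df": df, "p": 1.0}
    res = sps.kruskal(*groups)
    return {"H": float(res.statistic), "df": df, "p": float(res.pvalue)}


def build_report(
    features_index: pd.DataFrame,
    features_reference: pd.DataFrame,
    label_pairs: list[tuple[EpochStream, EpochStream]] | None = None,
    ci_bootstrap_n: int = 1000,
    seed: int = 0,
) -> dict:
    """Full agreement report: one block per feature plus per-epoch metrics.

    ``features_index``/``features_reference`` are subject-indexed feature
    tables; subjects present on only one device are skipped with a warning.
    ``label_pairs`` are (index fused stream, reference stream) tuples for
    the per-epoch diagnostic block.
    """
    common = features_index.index.intersection(features_reference.index)
    dropped = set(features_index.index).symmetric_difference(features_reference.index)
    if dropped:
        logger.warning("skipping %d unmatched subjects", len(dropped))
    fi = features_index.loc[common]
    fr = features_reference.loc[common]

    report: dict = {
        "schema_version": 1,
        "alpha": ALPHA,
        "multiple_testing_correction": "none",
        "n_subjects": int(len(common)),
        "features": {},
    }
    for feat in fi.columns:
        if feat not in fr.columns:
            continue
        series = PairedFeatureSeries(
            feat, fi[feat].to_numpy(float), fr[feat].to_numpy(float),
            subject_ids=list(common),
        )
        block: dict[str, object] = {"n_pairs": series.n}
        if series.n >= 2:
            block["mae"] = mae(series)
            block.update(correlation_battery(series))
            block.update(r_squared(series, ci_bootstrap_n, seed))
            if series.n >= 3:
                icc = icc_2way_absolute(np.column_stack([series.p, series.g]))
                block.update(icc)
                block["icc_band"] = icc_band(icc["icc"])
        report["features"][feat] = block

    if label_pairs:
        yp_all, yt_all, sc_all, subj = [], [], [], []
        for j, (pred, truth) in enumerate(label_pairs):
            common_t, ip, it = np.intersect1d(
                pred.times, truth.times, return_indices=True
            )
            keep = pred.valid_mask[ip] & truth.valid_mask[it]
            yp_all.append(pred.labels[ip][keep] == AF)
            yt_all.append(truth.labels[it][keep] == AF)
            sc_all.append(pred.prob_af[ip][keep])
            subj.append(np.full(int(keep.sum()), j))
        yp = np.concatenate(yp_all)
        yt = np.concatenate(yt_all)
        sc = np.concatenate(sc_all)
        block = _pooled_epoch_block(yp, yt, sc, ci_bootstrap_n, seed)
        report["epoch_metrics"] = block
    return report


def _pooled_epoch_block(yp, yt, sc, ci_bootstrap_n, seed) -> dict:
    n = yp.size
    out: dict[str, object] = {"n_epochs": int(n)}
    tp = int((yp & yt).sum())
    tn = int((~yp & ~yt).sum())
    npos, nneg = int(yt.sum()), int((~yt).sum())
    for name, k, m in (
        ("sensitivity", tp, npos),
        ("specificity", tn, nneg),
        ("accuracy", tp + tn, n),
    ):
        if m == 0:
            out[name], out[f"{name}_ci"] = math.nan, (math.nan, math.nan)
        else:
            out[name], out[f"{name}_ci"] = k / m, wilson_ci(k, m)
    finite = np.isfinite(sc)
    if npos and nneg and finite.any():
        rp = roc_pr(sc[finite], yt[finite], ci_bootstrap_n, seed)
        out["roc_auc"] = rp["roc_auc"]
        out["roc_auc_ci"] = rp["roc_auc_ci"]
        out["pr_auc"] = rp["pr_auc"]
    return out
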