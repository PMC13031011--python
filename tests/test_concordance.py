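"""Agreement and diagnostic statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from afburden import (
    PairedFeatureSeries,
    build_report,
    confusion_metrics,
    correlation_battery,
    extract_features,
    icc_2way_absolute,
    kruskal_wallis,
    mae,
    r_squared,
    roc_pr,
    wilson_ci,
)
from afburden.concordance import icc_band
from afburden.streams import AF, SINUS

from conftest import stream_from_string


def series(p, g):
    return PairedFeatureSeries("f", np.asarray(p, float), np.asarray(g, float))


# ------------------------------------------------------------------------ MAE

@pytest.mark.parametrize("p, g, expected", [
    ([0.2, 0.7], [0.2, 0.7], 0.0),
    ([0, 1], [1, 0], 1.0),
    ([0.3, 0.5], [0.1, 0.9], 0.3),
])
def test_mae_hand_cases(p, g, expected):
    assert mae(series(p, g)) == pytest.approx(expected)


def test_mae_empty_rejected():
    with pytest.raises(ValueError):
        mae(series([], []))


# ---------------------------------------------------------------- correlations

def test_battery_monotone_affine():
    p = np.array([1.0, 2, 3, 4, 5])
    out = correlation_battery(series(p, 2 * p + 1))
    assert out["pearson_r"] == pytest.approx(1.0)
    assert out["spearman_rho"] == pytest.approx(1.0)
    assert out["kendall_tau"] == pytest.approx(1.0)
    out = correlation_battery(series(p, -p))
    for key in ("pearson_r", "spearman_rho", "kendall_tau"):
        assert out[key] == pytest.approx(-1.0)


def test_battery_zero_variance_is_missing():
    out = correlation_battery(series([1, 1, 1], [1, 2, 3]))
    assert all(math.isnan(v) for v in out.values())


def _tau_b_oracle(x, y):
    """O(n^2) pair counting with tie correction."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / math.sqrt((n0 - tx) * (n0 - ty))


def test_kendall_tau_matches_pair_counting(rng):
    out = correlation_battery(series([1, 2, 3, 4], [1, 3, 2, 4]))
    assert out["kendall_tau"] == pytest.approx(2 / 3)
    for _ in range(30):
        n = int(rng.integers(5, 40))
        x = rng.integers(0, 8, n).astype(float)  # many ties
        y = rng.integers(0, 8, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        got = correlation_battery(series(x, y))["kendall_tau"]
        assert got == pytest.approx(_tau_b_oracle(x, y), abs=1e-12)


# ------------------------------------------------------------------ R squared

def test_r_squared_exact_linear_collapsed_ci():
    p = np.arange(10.0)
    out = r_squared(series(p, 3 * p - 2), ci_bootstrap_n=200, seed=0)
    assert out["r_squared"] == pytest.approx(1.0)
    assert out["r_squared_lo"] == pytest.approx(1.0)
    assert out["r_squared_hi"] == pytest.approx(1.0)


def test_r_squared_matches_sum_of_squares_oracle(rng):
    p = rng.uniform(size=40)
    g = 0.7 * p + rng.normal(0, 0.2, 40)
    out = r_squared(series(p, g), ci_bootstrap_n=10, seed=0)
    slope, intercept = np.polyfit(p, g, 1)
    resid = g - (slope * p + intercept)
    sst = ((g - g.mean()) ** 2).sum()
    oracle = 1 - (resid**2).sum() / sst
    assert out["r_squared"] == pytest.approx(oracle, abs=1e-12)


def test_r_squared_independent_noise_near_zero(rng):
    p = rng.normal(size=1000)
    g = rng.normal(size=1000)
    assert r_squared(series(p, g), ci_bootstrap_n=10, seed=0)["r_squared"] < 0.01


# ------------------------------------------------------------------------ ICC

def _icc_anova_oracle(X):
    n, k = X.shape
    gm = X.mean()
    rm, cm = X.mean(1), X.mean(0)
    msr = k * ((rm - gm) ** 2).sum() / (n - 1)
    msc = n * ((cm - gm) ** 2).sum() / (k - 1)
    mse = ((X - rm[:, None] - cm[None, :] + gm) ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc_identical_columns():
    X = np.column_stack([np.arange(10.0), np.arange(10.0)])
    assert icc_2way_absolute(X)["icc"] == pytest.approx(1.0)


def test_icc_penalizes_fixed_bias_unlike_pearson(rng):
    a = rng.normal(0, 1, 30)
    X = np.column_stack([a, a + 10])
    out = icc_2way_absolute(X)
    assert out["icc"] < 0.2
    assert sps.pearsonr(a, a + 10).statistic == pytest.approx(1.0)


def test_icc_matches_anova_oracle_and_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    for _ in range(20):
        X = rng.normal(size=(20, 2)) + rng.normal(size=(20, 1))
        out = icc_2way_absolute(X)
        assert out["icc"] == pytest.approx(_icc_anova_oracle(X), abs=1e-10)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(20), 2),
            "raters": ["p", "g"] * 20,
            "ratings": X.ravel(),
        })
        ref = pg.intraclass_corr(df, "targets", "raters", "ratings")
        icc_a1 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert out["icc"] == pytest.approx(icc_a1, abs=1e-8)
        assert out["icc_lo"] <= out["icc"] <= out["icc_hi"]


def test_icc_degenerate_matrix_missing():
    out = icc_2way_absolute(np.ones((5, 2)))
    assert math.isnan(out["icc"])


def test_icc_bands():
    assert icc_band(0.9) == "excellent"
    assert icc_band(0.6) == "moderate"
    assert icc_band(0.2) == "poor"


# ---------------------------------------------------------------- Wilson CIs

def test_wilson_closed_form():
    lo, hi = wilson_ci(50, 100)
    assert (round(lo, 4), round(hi, 4)) == (0.4038, 0.5962)


def test_wilson_boundary_zero():
    lo, _ = wilson_ci(0, 10)
    assert lo == 0.0


def test_wilson_respects_unit_interval():
    for n in range(1, 201, 7):
        for k in (0, 1, n // 2, n):
            lo, hi = wilson_ci(k, n)
            assert 0.0 <= lo <= k / n <= hi <= 1.0


# ---------------------------------------------------------- confusion metrics

def test_confusion_perfect_prediction():
    s = stream_from_string("AASSA")
    out = confusion_metrics(s, s)
    assert out["sensitivity"] == out["specificity"] == out["accuracy"] == 1.0
    assert out["sensitivity_ci"][0] < 1.0


def test_confusion_excludes_pairwise_invalid():
    pred = stream_from_string("AISA")
    truth = stream_from_string("ASIA")
    out = confusion_metrics(pred, truth)
    assert out["n_epochs"] == 2  # epochs 0 and 3 only
    assert out["accuracy"] == 1.0


# --------------------------------------------------------------------- ROC/PR

def test_roc_perfect_and_tied():
    out = roc_pr([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], ci_bootstrap_n=10)
    assert out["roc_auc"] == 1.0
    assert out["pr_auc"] == 1.0
    out = roc_pr([0.5] * 6, [1, 0, 1, 0, 1, 0], ci_bootstrap_n=10)
    assert out["roc_auc"] == 0.5


def _auc_mann_whitney(scores, y):
    s = np.asarray(scores, float)
    y = np.asarray(y, bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


def test_roc_auc_matches_rank_statistic(rng):
    for _ in range(30):
        n = int(rng.integers(6, 50))
        s = np.round(rng.uniform(size=n), 1)
        y = rng.uniform(size=n) < 0.5
        if y.all() or not y.any():
            continue
        out = roc_pr(s, y, ci_bootstrap_n=0)
        assert out["roc_auc"] == pytest.approx(_auc_mann_whitney(s, y), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    s = rng.uniform(size=50)
    y = rng.uniform(size=50) < 0.5
    a = roc_pr(s, y, ci_bootstrap_n=0)["roc_auc"]
    b = roc_pr(np.exp(3 * s), y, ci_bootstrap_n=0)["roc_auc"]
    assert a == pytest.approx(b, abs=1e-12)


# -------------------------------------------------------------- Kruskal-Wallis

def test_kruskal_hand_ranks():
    out = kruskal_wallis([1, 2], [3, 4])
    assert out["H"] == pytest.approx(2.4)
    assert out["df"] == 1


def test_kruskal_identical_values_convention():
    out = kruskal_wallis([5, 5, 5], [5, 5])
    assert out == {"H": 0.0, "df": 1, "p": 1.0}


def test_kruskal_two_groups_equals_squared_rank_sum_z(rng):
    for _ in range(20):
        n1, n2 = int(rng.integers(4, 20)), int(rng.integers(4, 20))
        a = rng.normal(size=n1)
        b = rng.normal(0.3, 1, size=n2)
        h = kruskal_wallis(a, b)["H"]
        z = sps.ranksums(a, b).statistic
        assert h == pytest.approx(z**2, abs=1e-9)


# ----------------------------------------------------------------- the report

def test_report_self_agreement():
    streams = [stream_from_string("AASSA" * 40, start=f"2024-01-0{k}T00:00")
               for k in (1, 2, 3)]
    feats = pd.DataFrame(
        {"burden_all": [0.1, 0.5, 0.9], "arv": [0.0, 0.2, 0.4]},
        index=["S1", "S2", "S3"])
    report = build_report(feats, feats,
                          label_pairs=[(s, s) for s in streams],
                          ci_bootstrap_n=20)
    for block in report["features"].values():
        assert block["mae"] == 0.0
        assert block["pearson_r"] == pytest.approx(1.0)
        assert block["icc"] == pytest.approx(1.0)
    em = report["epoch_metrics"]
    assert em["sensitivity"] == em["specificity"] == em["accuracy"] == 1.0


def test_report_single_subject_degenerates_gracefully():
    feats = pd.DataFrame({"burden_all": [0.3]}, index=["S1"])
    report = build_report(feats, feats)
    assert report["features"]["burden_all"] == {"n_pairs": 1}


def test_report_skips_unmatched_subjects(caplog):
    fi = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
    fr = pd.DataFrame({"f": [1.0, 2.0, 4.0]}, index=["a", "b", "d"])
    report = build_report(fi, fr)
    assert report["n_subjects"] == 2
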