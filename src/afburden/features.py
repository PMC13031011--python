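"""The 5-dimensional AF spatiotemporal progression features.

Fifteen metrics computed from a labeled epoch stream, grouped into five
dimensions of AF dynamics:

* **number** — how often AF occurs: AF-epoch ratio and the per-valid-epoch
  rate of episodes lasting >= 6 min and >= 1 h;
* **duration** — how much time is spent in AF: overall burden and the burden
  contributed by episodes >= 6 min / >= 1 h;
* **aggregation** — how burst-like AF time is: a Lorenz-type AF density index
  (0 = uniformly spread, 1 = maximally clustered);
* **circadian** — rhythm of AF over the clock: CV of episode onset times,
  signed day/night contrast (VOM), day-to-day / hour-to-hour burden
  variability, and average real variability (ARV) of the hourly burden;
* **tachycardia** — fraction of valid time/epochs with pulse rate > 120 bpm.

All ratios use *valid* epochs as denominator.  A feature whose preconditions
fail (e.g. CV of onsets with fewer than two episodes) is *missing* (NaN),
never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
import math

import numpy as np
import pandas as pd

from .streams import (
    AF,
    DAY_END_MIN,
    DAY_START_MIN,
    EpisodeList,
    EpochStream,
    TimeAccounting,
    extract_episodes,
    time_accounting,
)

__all__ = [
    "FEATURE_NAMES",
    "DIMENSIONS",
    "TACHY_BPM",
    "FeatureVector5D",
    "number_features",
    "duration_features",
    "af_density",
    "hourly_burden",
    "circadian_features",
    "tachycardia_features",
    "extract_features",
]

#: strict tachycardia threshold in bpm (epochs with pulse > 120 count)
TACHY_BPM = 120.0

DIMENSIONS: dict[str, tuple[str, ...]] = {
    "number": ("af_epoch_ratio", "episodes_ge6_ratio", "episodes_ge1h_ratio"),
    "duration": ("burden_all", "burden_ge6", "burden_ge1h"),
    "aggregation": ("af_density",),
    "circadian": (
        "cv_onset",
        "vom",
        "af_variability",
        "day_af_variability",
        "night_af_variability",
        "arv",
    ),
    "tachycardia": ("tachy_duration_ratio", "tachy_epoch_ratio"),
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    name for names in DIMENSIONS.values() for name in names
)


@dataclass
class FeatureVector5D:
    """The 15 spatiotemporal metrics for one subject-device stream.

    Missing features are NaN.
    """

    af_epoch_ratio: float = math.nan
    episodes_ge6_ratio: float = math.nan
    episodes_ge1h_ratio: float = math.nan
    burden_all: float = math.nan
    burden_ge6: float = math.nan
    burden_ge1h: float = math.nan
    af_density: float = math.nan
    cv_onset: float = math.nan
    vom: float = math.nan
    af_variability: float = math.nan
    day_af_variability: float = math.nan
    night_af_variability: float = math.nan
    arv: float = math.nan
    tachy_duration_ratio: float = math.nan
    tachy_epoch_ratio: float = math.nan

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _sd(x: np.ndarray) -> float:
    """Sample SD (ddof=1); NaN when fewer than two values."""
    x = np.asarray(x, float)
    if x.size < 2:
        return math.nan
    return float(np.std(x, ddof=1))


def number_features(episodes: EpisodeList, acct: TimeAccounting) -> dict[str, float]:
    """Episode-count rates per valid epoch.

    ``af_epoch_ratio`` is the fraction of valid epochs labeled AF; the other
    two are counts of episodes with duration >= 6 min / >= 60 min per valid
    epoch.
    """
    if acct.n_valid == 0:
        return dict.fromkeys(DIMENSIONS["number"], math.nan)
    dur = episodes.durations
    n_af = int(episodes.n_af_epochs.sum()) if len(episodes) else 0
    return {
        "af_epoch_ratio": n_af / acct.n_valid,
        "episodes_ge6_ratio": int((dur >= 6).sum()) / acct.n_valid,
        "episodes_ge1h_ratio": int((dur >= 60).sum()) / acct.n_valid,
    }


def duration_features(episodes: EpisodeList, acct: TimeAccounting) -> dict[str, float]:
    """AF burden (fraction of valid time in AF), overall and by episode stratum.

    Strata are closed lower bounds on episode duration: >= 6 min
    ("sustained") and >= 60 min ("prolonged"); AF time within an episode is
    its count of AF epochs, so bridged invalid minutes never contribute.
    """
    if acct.n_valid == 0:
        return dict.fromkeys(DIMENSIONS["duration"], math.nan)
    dur = episodes.durations
    naf = episodes.n_af_epochs
    total = int(naf.sum()) if len(episodes) else 0
    ge6 = int(naf[dur >= 6].sum()) if len(episodes) else 0
    ge1h = int(naf[dur >= 60].sum()) if len(episodes) else 0
    return {
        "burden_all": total / acct.n_valid,
        "burden_ge6": ge6 / acct.n_valid,
        "burden_ge1h": ge1h / acct.n_valid,
    }


def af_density(stream: EpochStream) -> float:
    """Burst-like concentration of AF time within valid monitoring time.

    Let u in [0, 1] index valid monitoring time and C(u) the fraction of
    total AF time accumulated by u (piecewise-linear through the per-epoch
    cumulative counts).  The index is

        density = integral |C(u) - u| du  /  ((1 - b) / 2),

    with b the overall burden.  The normalizer is the integral attained when
    all AF is one block at either end of monitoring, so density = 1 means
    maximal clustering; a perfectly interleaved stream gives 1/n_AF -> 0.
    Defined as 0 for b in {0, 1} (no contrast to localize).
    """
    valid = stream.valid_mask
    af = (stream.labels[valid] == AF).astype(float)
    n = af.size
    if n == 0:
        return math.nan
    total = af.sum()
    if total == 0 or total == n:
        return 0.0
    b = total / n
    c = np.concatenate([[0.0], np.cumsum(af) / total])
    u = np.arange(n + 1) / n
    d = c - u
    # exact integral of the piecewise-linear deviation, segment by segment
    d0, d1 = d[:-1], d[1:]
    same_sign = d0 * d1 >= 0
    seg = np.where(
        same_sign,
        (np.abs(d0) + np.abs(d1)) / 2.0,
        (d0**2 + d1**2) / (2.0 * np.maximum(np.abs(d0) + np.abs(d1), 1e-300)),
    )
    raw = float(seg.sum() / n)
    return raw / ((1.0 - b) / 2.0)


def hourly_burden(stream: EpochStream) -> tuple[np.ndarray, np.ndarray]:
    """Per-clock-hour AF burden series over hours with any valid epoch.

    Returns (hour timestamps as datetime64[h], AF minutes / valid minutes).
    """
    valid = stream.valid_mask
    if not valid.any():
        return (np.array([], dtype="datetime64[h]"), np.array([]))
    hours = stream.times[valid].astype("datetime64[h]")
    uh, inv = np.unique(hours, return_inverse=True)
    n_valid = np.bincount(inv)
    n_af = np.bincount(inv, weights=(stream.labels[valid] == AF).astype(float))
    return uh, n_af / n_valid


def circadian_features(
    stream: EpochStream,
    episodes: EpisodeList,
    window_min: int = 60,
) -> dict[str, float]:
    """Circadian-rhythm metrics of the AF process.

    * ``cv_onset``: sample SD / mean of episode onset clock times (minutes
      after midnight); needs >= 2 episodes.
    * ``vom``: signed day/night contrast (f_day - f_night)/(f_day + f_night)
      of AF-epoch frequency per valid epoch; 0 when both windows are AF-free.
    * ``af_variability``: SD of per-day burden when >= 2 sufficiently covered
      days exist, else SD of the hourly burden series.
    * ``day_af_variability`` / ``night_af_variability``: SD of the hourly
      burden restricted to [06:00, 22:00) / its complement.
    * ``arv``: mean absolute successive difference of the hourly burden over
      adjacent hours with valid data.
    """
    out = dict.fromkeys(DIMENSIONS["circadian"], math.nan)

    # CV of episode onset clock time
    if len(episodes) >= 2:
        onsets = np.array([e.onset for e in episodes], dtype="datetime64[m]")
        mod = ((onsets - onsets.astype("datetime64[D]")) / np.timedelta64(1, "m")).astype(float)
        mean = mod.mean()
        if mean > 0:
            out["cv_onset"] = _sd(mod) / mean

    valid = stream.valid_mask
    af = stream.labels == AF
    day = stream.is_day()

    # VOM: signed day/night AF-frequency contrast
    nd, nn = int((valid & day).sum()), int((valid & ~day).sum())
    f_day = int((af & day).sum()) / nd if nd else 0.0
    f_night = int((af & ~day).sum()) / nn if nn else 0.0
    out["vom"] = 0.0 if (f_day + f_night) == 0 else (f_day - f_night) / (f_day + f_night)

    uh, bh = hourly_burden(stream)
    if uh.size:
        hod = ((uh - uh.astype("datetime64[D]")) / np.timedelta64(1, "h")).astype(int)
        day_h = (hod >= DAY_START_MIN // 60) & (hod < DAY_END_MIN // 60)
        out["day_af_variability"] = _sd(bh[day_h])
        out["night_af_variability"] = _sd(bh[~day_h])
        adjacent = np.diff(uh) == np.timedelta64(1, "h")
        steps = np.abs(np.diff(bh))[adjacent]
        if steps.size:
            out["arv"] = float(steps.mean())

        # day-to-day burden when >= 2 days are at least half covered
        dates = stream.times[valid].astype("datetime64[D]")
        ud, dinv = np.unique(dates, return_inverse=True)
        nv = np.bincount(dinv)
        na = np.bincount(dinv, weights=af[valid].astype(float))
        covered = nv >= 720
        if covered.sum() >= 2:
            out["af_variability"] = _sd(na[covered] / nv[covered])
        else:
            out["af_variability"] = _sd(bh)
    return out


def tachycardia_features(stream: EpochStream) -> dict[str, float]:
    """Fraction of valid time / valid epochs with pulse rate strictly > 120 bpm.

    With 1-minute epochs the two ratios are identical by construction; both
    are reported because they are distinct constructs (time vs counts) that
    only coincide at this epoch length.
    """
    valid = stream.valid_mask
    pulse = stream.pulse_bpm[valid]
    if pulse.size == 0 or np.all(np.isnan(pulse)):
        return dict.fromkeys(DIMENSIONS["tachycardia"], math.nan)
    with np.errstate(invalid="ignore"):
        n_tachy = int(np.count_nonzero(pulse > TACHY_BPM))
    ratio = n_tachy / pulse.size
    return {"tachy_duration_ratio": ratio, "tachy_epoch_ratio": ratio}


@dataclass
class FeatureConfig:
    bridging_gap_max: int = 3
    window_min: int = 60


def extract_features(
    stream: EpochStream, cfg: FeatureConfig | None = None
) -> FeatureVector5D:
    """Episode extraction plus all five feature groups for one stream."""
    cfg = cfg or FeatureConfig()
    acct = time_accounting(stream)
    if acct.n_valid == 0:
        return FeatureVector5D()
    episodes = extract_episodes(stream, cfg.bridging_gap_max)
    values: dict[str, float] = {}
    values.update(number_features(episodes, acct))
    values.update(duration_features(episodes, acct))
    values["af_density"] = af_density(stream)
    values.update(circadian_features(stream, episodes, cfg.window_min))
    values.update(tachycardia_features(stream))
    return FeatureVector5D(**values)
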