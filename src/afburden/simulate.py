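"""Synthetic paired wearable/Holter cohort generator.

Emulates a paroxysmal-AF monitoring study in which every subject wears an
optical (PPG) index device synchronized with a reference Holter channel:

* AF episode onsets follow an inhomogeneous Poisson process with a 24-hour
  cosine rate modulation (nocturnal predominance by default);
* episode durations come from a three-component lognormal mixture spanning
  the < 6 min / 6 min-1 h / >= 1 h strata;
* pulse rates are drawn per epoch from a sinus or a (tachycardic) AF
  distribution according to the true rhythm state;
* the index channel is degraded by daytime-dominant motion-artifact masking
  (about 30% of epochs invalid overall by default) and graded classifier
  noise on the AF probability; the reference channel sees only a small
  artifact rate and no classifier noise;
* clinical labels (EHRA symptom class, event flag, risk profile, treatment)
  are generated with a logistic link from the true burden so the downstream
  score and cutoff machinery has a recoverable signal.

All randomness flows from one integer seed; simulating the same
(seed, subject_index) twice is bit-identical.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .streams import AF, INVALID, SINUS, EPOCH_MIN, EpochStream

__all__ = [
    "SimParams",
    "ClinicalLabels",
    "SubjectData",
    "Cohort",
    "simulate_subject",
    "degrade_to_device",
    "simulate_cohort",
]

_T0 = np.datetime64("2024-01-01T00:00", "m")


class ParameterError(ValueError):
    """Pathological simulation parameters (e.g. expected burden >= 1)."""


@dataclass
class SimParams:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a paroxysmal-AF cohort under 24-hour synchronized
    monitoring: sparse nocturnally-modulated episode onsets, a duration
    mixture with mass in all three strata, tachycardic AF pulse rates, and
    ~30% overall motion-artifact masking concentrated in the daytime.
    """

    n_subjects: int = 40
    days_per_subject: int = 1
    #: episode onsets per hour before circadian modulation
    base_onset_rate: float = 0.15
    circadian_amplitude: float = 0.5
    circadian_phase_hr: float = 3.0
    #: lognormal mixture over episode duration (minutes)
    duration_weights: tuple[float, ...] = (0.50, 0.35, 0.15)
    duration_log_means: tuple[float, ...] = (
        math.log(2.5),
        math.log(20.0),
        math.log(150.0),
    )
    duration_log_sds: tuple[float, ...] = (0.5, 0.5, 0.6)
    sinus_hr_mean: float = 75.0
    sinus_hr_sd: float = 8.0
    af_hr_mean: float = 110.0
    af_hr_sd: float = 18.0
    #: documented tachycardia threshold used by downstream features
    tachy_floor_bpm: float = 120.0
    artifact_rate_day: float = 0.40
    artifact_rate_night: float = 0.10
    ref_artifact_rate: float = 0.02
    #: index-classifier probability centers sit at 0.5 +- classifier_margin
    classifier_margin: float = 0.3
    prob_noise_sd: float = 0.15
    flip_prob: float = 0.0
    noise_mode: str = "gaussian"  # "gaussian" | "flip"
    #: logistic link from true burden to event probability
    event_alpha: float = -2.5
    event_beta: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.days_per_subject < 1:
            raise ParameterError("n_subjects and days_per_subject must be >= 1")
        if self.base_onset_rate < 0:
            raise ParameterError("base_onset_rate must be >= 0")
        if not (0.0 <= self.circadian_amplitude < 1.0):
            raise ParameterError("circadian_amplitude must be in [0, 1)")
        w = np.asarray(self.duration_weights, float)
        if w.size != len(self.duration_log_means) or w.size != len(self.duration_log_sds):
            raise ParameterError("duration mixture component counts differ")
        if not math.isclose(w.sum(), 1.0, abs_tol=1e-9) or (w < 0).any():
            raise ParameterError("duration weights must be >= 0 and sum to 1")
        for name in ("artifact_rate_day", "artifact_rate_night", "ref_artifact_rate",
                     "flip_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.noise_mode not in ("gaussian", "flip"):
            raise ParameterError("noise_mode must be 'gaussian' or 'flip'")
        if self.expected_burden() >= 1.0:
            raise ParameterError(
                "expected AF burden >= 1: onset rate and duration mixture "
                "saturate the monitoring time"
            )

    def mean_duration_min(self) -> float:
        w = np.asarray(self.duration_weights, float)
        mu = np.asarray(self.duration_log_means, float)
        sd = np.asarray(self.duration_log_sds, float)
        return float((w * np.exp(mu + sd**2 / 2)).sum())

    def expected_burden(self) -> float:
        """Stationary expected burden (rate x mean duration), ignoring overlap."""
        return self.base_onset_rate * self.mean_duration_min() / 60.0


@dataclass
class ClinicalLabels:
    """One subject's clinical annotation row."""

    subject_id: str
    ehra_class: int | None  # ordinal 0..4; assigned at cohort level
    event_flag: bool
    risk_profile: str  # rhythm_rate | thromboembolism | other
    treatment: str  # none | drug | ablation


@dataclass
class SubjectData:
    subject_id: str
    truth: EpochStream
    index: EpochStream
    reference: EpochStream
    labels: ClinicalLabels


@dataclass
class Cohort:
    params: SimParams
    subjects: list[SubjectData] = field(default_factory=list)

    def labels_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.labels.subject_id,
                "ehra_class": s.labels.ehra_class,
                "event_flag": int(s.labels.event_flag),
                "risk_profile": s.labels.risk_profile,
                "treatment": s.labels.treatment,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)


def _subject_rng(params: SimParams, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, subject_index])


def _true_burden(stream: EpochStream) -> float:
    return float((stream.labels == AF).mean()) if stream.n_total else 0.0


def simulate_subject(
    params: SimParams, subject_index: int, return_draws: bool = False
):
    """Noiseless truth stream plus clinical labels for one subject.

    Onsets are drawn by thinning a homogeneous Poisson process against
    lambda(t) = base_onset_rate * (1 + A cos(2 pi (t - phase)/24 h)); episode
    durations come from the lognormal mixture (rounded to whole minutes,
    >= 1); overlapping episodes merge.  ``ehra_class`` is left unset here
    because its quartile binning is a cohort-level construct.

    With ``return_draws=True`` the raw (onset minute, duration) draws are
    returned as a third element, before merging/clipping, for recovery
    checks against the programmed process.
    """
    rng = _subject_rng(params, subject_index)
    n_min = params.days_per_subject * 1440
    af = np.zeros(n_min, dtype=bool)
    draws: list[tuple[float, int]] = []

    lam_max_per_min = params.base_onset_rate * (1.0 + params.circadian_amplitude) / 60.0
    n_cand = rng.poisson(lam_max_per_min * n_min)
    if n_cand and params.base_onset_rate > 0:
        t_cand = np.sort(rng.uniform(0.0, n_min, size=n_cand))  # minutes
        t_hr = (t_cand / 60.0) % 24.0
        lam = params.base_onset_rate / 60.0 * (
            1.0
            + params.circadian_amplitude
            * np.cos(2.0 * np.pi * (t_hr - params.circadian_phase_hr) / 24.0)
        )
        keep = rng.uniform(size=n_cand) < lam / lam_max_per_min
        onsets = t_cand[keep]
        comp = rng.choice(len(params.duration_weights), size=onsets.size,
                          p=params.duration_weights)
        mu = np.asarray(params.duration_log_means)[comp]
        sd = np.asarray(params.duration_log_sds)[comp]
        durations = np.maximum(1, np.rint(rng.lognormal(mu, sd)).astype(int))
        draws = list(zip(onsets.tolist(), durations.tolist()))
        for onset, dur in zip(np.floor(onsets).astype(int), durations):
            af[onset : min(onset + dur, n_min)] = True

    labels = np.where(af, AF, SINUS).astype(np.int8)
    pulse = np.where(
        af,
        rng.normal(params.af_hr_mean, params.af_hr_sd, n_min),
        rng.normal(params.sinus_hr_mean, params.sinus_hr_sd, n_min),
    )
    pulse = np.clip(pulse, 30.0, None)
    subject_id = f"S{subject_index:04d}"
    truth = EpochStream(
        subject_id=subject_id,
        device="TRUTH",
        times=_T0 + np.arange(n_min) * EPOCH_MIN,
        labels=labels,
        prob_af=af.astype(float),
        pulse_bpm=pulse,
        quality=np.ones(n_min),
    )

    burden = _true_burden(truth)
    p_event = 1.0 / (1.0 + math.exp(-(params.event_alpha + params.event_beta * burden)))
    event = bool(rng.uniform() < p_event)
    risk = str(rng.choice(["rhythm_rate", "thromboembolism", "other"],
                          p=[0.7, 0.1, 0.2]))
    treatment = str(rng.choice(["none", "drug", "ablation"], p=[0.5, 0.3, 0.2]))
    labels_row = ClinicalLabels(
        subject_id=subject_id,
        ehra_class=None,
        event_flag=event,
        risk_profile=risk,
        treatment=treatment,
    )
    if return_draws:
        return truth, labels_row, draws
    return truth, labels_row


def degrade_to_device(
    truth: EpochStream,
    params: SimParams,
    device: str = "INDEX",
    rng: np.random.Generator | None = None,
) -> EpochStream:
    """Pass the noiseless truth through one device's observation channel.

    INDEX: epochs go INVALID independently at the day/night artifact rates;
    surviving epochs carry prob_af centered at 0.5 +- classifier_margin
    (sign by true rhythm) plus Gaussian noise clamped to [0, 1] (or hard
    label flips in ``noise_mode="flip"``), thresholded at 0.5 into labels.
    REFERENCE: a single low artifact rate and no classifier noise.
    """
    if rng is None:
        tag = zlib.crc32(f"{truth.subject_id}|{device}".encode())
        rng = np.random.default_rng([params.seed, tag])
    out = truth.copy()
    out.device = device
    n = out.n_total
    truth_af = truth.labels == AF

    if device == "REFERENCE":
        invalid = rng.uniform(size=n) < params.ref_artifact_rate
        prob = truth_af.astype(float)
        labels = truth.labels.copy()
    else:
        day = truth.is_day()
        rate = np.where(day, params.artifact_rate_day, params.artifact_rate_night)
        invalid = rng.uniform(size=n) < rate
        if params.noise_mode == "flip":
            flip = rng.uniform(size=n) < params.flip_prob
            obs_af = truth_af ^ flip
            prob = obs_af.astype(float)
        else:
            center = 0.5 + params.classifier_margin * np.where(truth_af, 1.0, -1.0)
            prob = np.clip(center + rng.normal(0.0, params.prob_noise_sd, n), 0.0, 1.0)
            obs_af = prob >= 0.5
        labels = np.where(obs_af, AF, SINUS).astype(np.int8)

    labels[invalid] = INVALID
    prob = prob.astype(float)
    prob[invalid] = np.nan
    quality = np.where(
        invalid, rng.uniform(0.0, 0.4, n), rng.uniform(0.6, 1.0, n)
    )
    out.labels = labels
    out.prob_af = prob
    out.quality = quality
    out.pulse_bpm = truth.pulse_bpm.copy()
    out.pulse_bpm[invalid] = np.nan
    return out


def simulate_cohort(params: SimParams) -> Cohort:
    """Paired INDEX/REFERENCE streams plus a clinical-label table.

    EHRA classes are assigned from cohort quartiles of true burden among
    subjects with any AF (classes I-IV, with 10% ordinal jitter); subjects
    with zero burden get class 0.
    """
    if params.n_subjects < 2:
        raise ParameterError("cohort needs >= 2 subjects (weight derivation "
                             "requires between-subject variance)")
    subjects: list[SubjectData] = []
    burdens = np.empty(params.n_subjects)
    for i in range(params.n_subjects):
        truth, labels = simulate_subject(params, i)
        index = degrade_to_device(truth, params, "INDEX")
        reference = degrade_to_device(truth, params, "REFERENCE")
        burdens[i] = _true_burden(truth)
        subjects.append(SubjectData(truth.subject_id, truth, index, reference, labels))

    rng = np.random.default_rng([params.seed, 2**20])
    pos = burdens > 0
    if pos.any():
        edges = np.quantile(burdens[pos], [0.25, 0.5, 0.75])
        classes = np.where(pos, 1 + np.searchsorted(edges, burdens), 0)
    else:
        classes = np.zeros(params.n_subjects, dtype=int)
    jitter = rng.uniform(size=params.n_subjects) < 0.10
    shift = rng.choice([-1, 1], size=params.n_subjects)
    classes = np.where(pos & jitter, np.clip(classes + shift, 1, 4), classes)
    for s, c in zip(subjects, classes):
        s.labels.ehra_class = int(c)
    return Cohort(params=params, subjects=subjects)
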