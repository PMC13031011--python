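"""Per-minute rhythm epoch streams, AF episode extraction and time accounting.

A monitoring channel (wrist wearable or ambulatory Holter) is represented as a
uniform sequence of 1-minute epochs.  Each epoch carries a rhythm label
(``AF`` / ``SINUS`` / ``INVALID``), an optional AF probability, an optional
mean pulse rate (bpm) and a signal-quality score in [0, 1].  Epochs are
left-closed right-open 1-minute windows; timestamps are local clock time,
because the circadian features downstream are clock-time constructs.

INVALID epochs contribute to *total* monitoring time but never to *valid*
time; every burden-type ratio in the package uses valid time as denominator.

An AF *episode* is a maximal run of AF epochs.  Short runs of INVALID epochs
(unreadable signal inside one physiological episode) may be bridged; a
confirmed SINUS epoch always terminates an episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AF",
    "SINUS",
    "INVALID",
    "LABEL_TO_CODE",
    "CODE_TO_LABEL",
    "DAY_START_MIN",
    "DAY_END_MIN",
    "EPOCH_MIN",
    "MalformedStreamError",
    "EpochStream",
    "Episode",
    "EpisodeList",
    "TimeAccounting",
    "extract_episodes",
    "time_accounting",
]

# integer label codes (compact, vectorizable)
AF: int = 1
SINUS: int = 0
INVALID: int = -1

LABEL_TO_CODE = {"AF": AF, "SINUS": SINUS, "INVALID": INVALID}
CODE_TO_LABEL = {v: k for k, v in LABEL_TO_CODE.items()}

#: daytime clock window [06:00, 22:00) in minutes after midnight; the night
#: window is the complement [22:00, 06:00).
DAY_START_MIN = 6 * 60
DAY_END_MIN = 22 * 60

EPOCH_MIN = np.timedelta64(1, "m")


class MalformedStreamError(ValueError):
    """Raised for non-monotone, irregular or inconsistent epoch streams."""


def _as_float(x, n: int, name: str) -> np.ndarray:
    if x is None:
        return np.full(n, np.nan)
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise MalformedStreamError(f"{name} has shape {arr.shape}, expected ({n},)")
    return arr


@dataclass
class EpochStream:
    """One device's per-minute epoch record for a single subject.

    Parameters
    ----------
    subject_id : str
    device : str
        ``"INDEX"`` (wearable) or ``"REFERENCE"`` (Holter).
    times : ndarray of datetime64[m]
        Left edges of the 1-minute windows; strictly increasing with
        constant 1-minute spacing (readers fill gaps with INVALID epochs).
    labels : ndarray of int8
        Codes ``AF``/``SINUS``/``INVALID``.
    prob_af, pulse_bpm, quality : ndarray of float
        Per-epoch AF probability in [0, 1] (NaN = absent), mean pulse rate
        in bpm (NaN = absent) and signal quality in [0, 1].
    """

    subject_id: str
    device: str
    times: np.ndarray
    labels: np.ndarray
    prob_af: np.ndarray = None  # type: ignore[assignment]
    pulse_bpm: np.ndarray = None  # type: ignore[assignment]
    quality: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[m]")
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n = self.labels.size
        if self.times.shape != (n,):
            raise MalformedStreamError("times and labels lengths differ")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= np.timedelta64(0, "m")):
                raise MalformedStreamError("timestamps not strictly increasing")
            if np.any(dt != EPOCH_MIN):
                raise MalformedStreamError(
                    "epoch spacing is not a constant 1 minute (fill gaps with "
                    "INVALID epochs)"
                )
        if not np.isin(self.labels, (AF, SINUS, INVALID)).all():
            raise MalformedStreamError("unknown label code present")
        self.prob_af = _as_float(self.prob_af, n, "prob_af")
        self.pulse_bpm = _as_float(self.pulse_bpm, n, "pulse_bpm")
        if self.quality is None:
            self.quality = np.ones(n)
        self.quality = _as_float(self.quality, n, "quality")
        finite = np.isfinite(self.prob_af)
        if np.any((self.prob_af[finite] < 0) | (self.prob_af[finite] > 1)):
            raise MalformedStreamError("prob_af outside [0, 1]")
        qf = np.isfinite(self.quality)
        if np.any((self.quality[qf] < 0) | (self.quality[qf] > 1)):
            raise MalformedStreamError("quality outside [0, 1]")

    # -- derived views ---------------------------------------------------

    @property
    def n_total(self) -> int:
        return int(self.labels.size)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != INVALID

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def minute_of_day(self) -> np.ndarray:
        """Minutes after local midnight for every epoch."""
        days = self.times.astype("datetime64[D]")
        return ((self.times - days) / EPOCH_MIN).astype(np.int64)

    def is_day(self) -> np.ndarray:
        """Boolean mask: epoch start lies in the daytime window [06:00, 22:00)."""
        m = self.minute_of_day()
        return (m >= DAY_START_MIN) & (m < DAY_END_MIN)

    def copy(self) -> "EpochStream":
        return replace(
            self,
            times=self.times.copy(),
            labels=self.labels.copy(),
            prob_af=self.prob_af.copy(),
            pulse_bpm=self.pulse_bpm.copy(),
            quality=self.quality.copy(),
        )

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_labels(
        cls,
        labels: Sequence,
        start: str = "2024-01-01T00:00",
        subject_id: str = "S0",
        device: str = "INDEX",
        prob_af=None,
        pulse_bpm=None,
        quality=None,
    ) -> "EpochStream":
        """Build a stream from label codes or strings at 1-minute cadence."""
        codes = [LABEL_TO_CODE[x] if isinstance(x, str) else int(x) for x in labels]
        n = len(codes)
        t0 = np.datetime64(start, "m")
        times = t0 + np.arange(n) * EPOCH_MIN
        return cls(subject_id, device, times, np.asarray(codes, np.int8),
                   prob_af, pulse_bpm, quality)


@dataclass(frozen=True)
class Episode:
    """A maximal (possibly invalid-bridged) run of AF epochs.

    ``duration_min`` spans onset to the last AF epoch inclusive, so bridged
    INVALID minutes may inflate the duration but never ``n_af_epochs``.
    """

    onset: np.datetime64
    duration_min: int
    n_af_epochs: int

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValueError("duration_min must be >= 1")
        if not (1 <= self.n_af_epochs <= self.duration_min):
            raise ValueError("need 1 <= n_af_epochs <= duration_min")


@dataclass
class EpisodeList:
    """Ordered, non-overlapping AF episodes extracted with one bridging rule."""

    episodes: list[Episode] = field(default_factory=list)
    bridging_gap_max: int = 3

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self) -> Iterator[Episode]:
        return iter(self.episodes)

    def __getitem__(self, i):
        return self.episodes[i]

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration_min for e in self.episodes], dtype=int)

    @property
    def n_af_epochs(self) -> np.ndarray:
        return np.array([e.n_af_epochs for e in self.episodes], dtype=int)


@dataclass(frozen=True)
class TimeAccounting:
    """Epoch counts split by validity and clock window."""

    n_total: int
    n_valid: int
    n_valid_day: int
    n_valid_night: int


def extract_episodes(stream: EpochStream, bridging_gap_max: int = 3) -> EpisodeList:
    """Extract maximal AF runs, bridging short INVALID gaps.

    Two AF runs separated only by ``<= bridging_gap_max`` consecutive INVALID
    epochs are merged into one episode; any SINUS epoch in between, or a
    longer invalid gap, separates them.  With ``bridging_gap_max = 0`` this
    is classical maximal-run extraction.
    """
    if bridging_gap_max < 0:
        raise ValueError("bridging_gap_max must be >= 0")
    labels = stream.labels
    af_idx = np.flatnonzero(labels == AF)
    episodes: list[Episode] = []
    if af_idx.size == 0:
        return EpisodeList([], bridging_gap_max)

    def close(first: int, last: int) -> None:
        n_af = int(np.count_nonzero(labels[first : last + 1] == AF))
        episodes.append(
            Episode(
                onset=stream.times[first],
                duration_min=int(last - first + 1),
                n_af_epochs=n_af,
            )
        )

    first = last = int(af_idx[0])
    for i in af_idx[1:]:
        i = int(i)
        gap = labels[last + 1 : i]
        if gap.size <= bridging_gap_max and np.all(gap == INVALID):
            last = i
        else:
            close(first, last)
            first = last = i
    close(first, last)
    return EpisodeList(episodes, bridging_gap_max)


def time_accounting(stream: EpochStream) -> TimeAccounting:
    """Count total/valid epochs and split valid epochs by clock window."""
    valid = stream.valid_mask
    day = stream.is_day()
    n_valid_day = int(np.count_nonzero(valid & day))
    n_valid = int(valid.sum())
    return TimeAccounting(
        n_total=stream.n_total,
        n_valid=n_valid,
        n_valid_day=n_valid_day,
        n_valid_night=n_valid - n_valid_day,
    )
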