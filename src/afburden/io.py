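"""Epoch-stream CSV dialect: reading, validation, gap filling, writing.

One file holds one subject-device stream with the header

    subject_id,device,start_time,label,prob_af,pulse_bpm,quality

``start_time`` is ISO-8601 at minute precision; ``label`` is one of
AF/SINUS/INVALID; ``prob_af`` and ``pulse_bpm`` may be empty.  Readers fill
timestamp gaps with INVALID epochs so spacing is a uniform 1 minute (every
ratio downstream needs a well-defined total-time denominator); writers emit
the same dialect with a stable column order and '.' decimals, so
write -> read is the identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .streams import (
    CODE_TO_LABEL,
    EPOCH_MIN,
    INVALID,
    LABEL_TO_CODE,
    EpochStream,
)

__all__ = ["HEADER", "EpochCSVError", "read_epoch_csv", "write_epoch_csv"]

HEADER = ["subject_id", "device", "start_time", "label", "prob_af", "pulse_bpm", "quality"]

_DEVICES = {"INDEX", "REFERENCE", "TRUTH"}


class EpochCSVError(ValueError):
    """Epoch CSV does not match the documented dialect."""


def _err(line: int, msg: str) -> EpochCSVError:
    return EpochCSVError(f"line {line}: {msg}")


def read_epoch_csv(path) -> EpochStream:
    """Parse and validate one epoch-stream CSV; fill gaps with INVALID epochs.

    Raises :class:`EpochCSVError` naming the offending line for any header,
    enum, timestamp or ordering violation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != HEADER:
        raise EpochCSVError(
            f"bad header {list(df.columns)}; expected {HEADER}"
        )
    if len(df) == 0:
        raise EpochCSVError("empty stream")
    if df["subject_id"].nunique() != 1 or df["device"].nunique() != 1:
        raise EpochCSVError("file must contain exactly one subject-device stream")
    subject_id = df["subject_id"].iloc[0]
    device = df["device"].iloc[0]
    if device not in _DEVICES:
        raise _err(2, f"unknown device {device!r}")

    n = len(df)
    times = np.empty(n, dtype="datetime64[m]")
    labels = np.empty(n, dtype=np.int8)
    prob = np.full(n, np.nan)
    pulse = np.full(n, np.nan)
    quality = np.full(n, np.nan)
    for i in range(n):
        line = i + 2  # header is line 1
        try:
            times[i] = np.datetime64(df["start_time"].iloc[i], "m")
        except ValueError:
            raise _err(line, f"bad timestamp {df['start_time'].iloc[i]!r}") from None
        lab = df["label"].iloc[i]
        if lab not in LABEL_TO_CODE:
            raise _err(line, f"bad label {lab!r} (expected AF/SINUS/INVALID)")
        labels[i] = LABEL_TO_CODE[lab]
        for col, target in (("prob_af", prob), ("pulse_bpm", pulse), ("quality", quality)):
            cell = df[col].iloc[i]
            if cell != "":
                try:
                    target[i] = float(cell)
                except ValueError:
                    raise _err(line, f"bad {col} value {cell!r}") from None
    quality = np.where(np.isnan(quality), 1.0, quality)

    dt = np.diff(times)
    if np.any(dt <= np.timedelta64(0, "m")):
        bad = int(np.flatnonzero(dt <= np.timedelta64(0, "m"))[0]) + 1
        raise _err(bad + 2, "timestamps not strictly increasing")

    # fill gaps with INVALID epochs
    span = int((times[-1] - times[0]) / EPOCH_MIN) + 1
    if span != n:
        full_times = times[0] + np.arange(span) * EPOCH_MIN
        pos = ((times - times[0]) / EPOCH_MIN).astype(int)
        full_labels = np.full(span, INVALID, dtype=np.int8)
        full_prob = np.full(span, np.nan)
        full_pulse = np.full(span, np.nan)
        full_quality = np.zeros(span)
        full_labels[pos] = labels
        full_prob[pos] = prob
        full_pulse[pos] = pulse
        full_quality[pos] = quality
        times, labels = full_times, full_labels
        prob, pulse, quality = full_prob, full_pulse, full_quality

    try:
        return EpochStream(subject_id, device, times, labels, prob, pulse, quality)
    except ValueError as exc:
        raise EpochCSVError(str(exc)) from exc


def write_epoch_csv(stream: EpochStream, path) -> None:
    """Write one stream in the documented dialect (round-trip exact)."""
    times = pd.DatetimeIndex(stream.times).strftime("%Y-%m-%dT%H:%M")
    df = pd.DataFrame(
        {
            "subject_id": stream.subject_id,
            "device": stream.device,
            "start_time": times,
            "label": [CODE_TO_LABEL[c] for c in stream.labels],
            "prob_af": stream.prob_af,
            "pulse_bpm": stream.pulse_bpm,
            "quality": stream.quality,
        }
    )
    df.to_csv(path, index=False, na_rep="")
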