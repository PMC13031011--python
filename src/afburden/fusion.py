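"""Multiscale fusion of per-epoch AF evidence.

Three stages turn raw per-minute classifier output into a clean rhythm
stream:

1. **quality gating** — epochs below a signal-quality floor are relabeled
   INVALID and drop out of every downstream denominator;
2. **per-epoch classification** — any classifier satisfying the contract
   "epoch with >= 12 interbeat intervals -> AF probability" plugs in here; a
   deterministic interbeat-interval-irregularity scorer is provided as a
   reference stand-in (it is NOT the trained model of any specific device);
3. **contextual fusion** — each valid epoch's probability is replaced by a
   validity-masked weighted mean over a short symmetric window of neighbors,
   exploiting the temporal continuity of AF episodes, then thresholded into
   AF/SINUS labels.

Yield-rate accounting (valid epochs / total epochs, overall and by clock
window) quantifies tolerance to motion artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .streams import AF, INVALID, SINUS, EpochStream

__all__ = [
    "FusionConfig",
    "InsufficientDataError",
    "gate_quality",
    "classify_epoch_reference",
    "contextual_fuse",
    "yield_rate",
]


class InsufficientDataError(ValueError):
    """An epoch carries too few interbeat intervals to classify."""


@dataclass
class FusionConfig:
    """Parameters of the contextual-fusion stage.

    ``neighbor_weights[k]`` weights the epochs at offset +-k; index 0 is the
    epoch itself.  Defaults (triangular 3-2-1 over a +-2-epoch window,
    threshold 0.5) keep the fused support shorter than 6 minutes so genuine
    short episodes remain detectable.
    """

    quality_min: float = 0.5
    window: int = 2
    neighbor_weights: tuple[float, ...] = (3.0, 2.0, 1.0)
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if len(self.neighbor_weights) != self.window + 1:
            raise ValueError("need window + 1 neighbor weights (self first)")
        w = np.asarray(self.neighbor_weights, float)
        if not (np.isfinite(w).all() and (w > 0).all()):
            raise ValueError("neighbor weights must be finite and positive")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValueError("decision_threshold must be in (0, 1)")


def gate_quality(stream: EpochStream, quality_min: float) -> EpochStream:
    """Relabel epochs with quality below ``quality_min`` as INVALID.

    Idempotent; all other epochs pass through unchanged.
    """
    out = stream.copy()
    low = out.quality < quality_min
    out.labels[low] = INVALID
    return out


def classify_epoch_reference(ibi_ms) -> float:
    """Deterministic AF probability from interbeat-interval irregularity.

    A reference stand-in for the per-epoch classifier contract: it combines
    the normalized mean absolute circular successive difference of the
    intervals with the Shannon entropy of the normalized-difference
    histogram, squashed through a fixed logistic.  Circular differences make
    the score exactly invariant to duplicating the sequence, so it is
    length-adaptive by construction.  Higher irregularity => higher
    probability.  This scorer satisfies the classifier contract only; it is
    not a trained model.
    """
    x = np.asarray(ibi_ms, dtype=float)
    if x.size < 12:
        raise InsufficientDataError(
            f"need >= 12 interbeat intervals, got {x.size}"
        )
    if np.any((x < 250.0) | (x > 2500.0)):
        raise ValueError("interbeat intervals must lie in 250-2500 ms")
    mean = x.mean()
    diff = np.diff(x, append=x[:1]) / mean  # circular successive differences
    irregularity = float(np.abs(diff).mean())
    bins = np.linspace(-1.0, 1.0, 25)
    counts, _ = np.histogram(np.clip(diff, -1.0, 1.0), bins=bins)
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log(p)).sum() / np.log(bins.size - 1))
    score = 14.0 * irregularity + 2.0 * entropy - 3.0
    return float(1.0 / (1.0 + np.exp(-score)))


def contextual_fuse(stream: EpochStream, cfg: FusionConfig | None = None) -> EpochStream:
    """Smooth per-epoch AF probabilities over a symmetric neighbor window.

    For valid epoch i the fused probability is

        sum_{|k| <= W, i+k valid} w_|k| p_{i+k}  /  sum w_|k|,

    with invalid neighbors excluded from numerator and denominator, and the
    label set to AF iff the fused probability reaches the decision
    threshold.  INVALID epochs are untouched.  Valid epochs missing a
    probability fall back to their {0, 1} label encoding, so the stage
    degrades gracefully to weighted majority voting.
    """
    cfg = cfg or FusionConfig()
    out = stream.copy()
    valid = out.valid_mask
    p = out.prob_af.copy()
    need = valid & ~np.isfinite(p)
    p[need] = (out.labels[need] == AF).astype(float)

    w = np.asarray(cfg.neighbor_weights, float)
    pv = np.where(valid, p, 0.0)
    vv = valid.astype(float)
    num = w[0] * pv.copy()
    den = w[0] * vv.copy()
    for k in range(1, cfg.window + 1):
        num[k:] += w[k] * pv[:-k]
        den[k:] += w[k] * vv[:-k]
        num[:-k] += w[k] * pv[k:]
        den[:-k] += w[k] * vv[k:]

    fused = np.full(out.n_total, np.nan)
    fused[valid] = num[valid] / den[valid]
    out.prob_af = fused
    out.labels[valid] = np.where(
        fused[valid] >= cfg.decision_threshold, AF, SINUS
    ).astype(np.int8)
    return out


def yield_rate(stream: EpochStream) -> dict[str, float]:
    """Fraction of epochs with a valid rhythm decision, overall and by window.

    ``day``/``night`` restrict both numerator and denominator to the
    [06:00, 22:00) window and its complement; a window with no epochs yields
    NaN for that rate.
    """
    if stream.n_total == 0:
        raise ValueError("yield rate undefined for an empty stream")
    valid = stream.valid_mask
    day = stream.is_day()
    out = {"overall": float(valid.mean())}
    for name, mask in (("day", day), ("night", ~day)):
        n = int(mask.sum())
        out[name] = float(valid[mask].sum() / n) if n else float("nan")
    return out
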