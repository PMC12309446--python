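"""FASTER-style artifact detection.

FASTER (Fully Automated Statistical Thresholding for EEG artifact
Rejection) standardizes a per-channel or per-epoch statistic into a
Z-score across channels (or epochs) and flags entries whose |Z|
exceeds 3.

Channel criteria (four): mean absolute pairwise correlation, signal
variance, Hurst exponent, and mean power in the 48-62 Hz powerline
band (the band covers both 50 and 60 Hz mains).

Epoch criteria (three): amplitude range, within-epoch variance, and
the deviation parameter — the difference between an epoch's mean value
and the channel's average epoch mean — each averaged across channels
before standardizing over epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from eegqc.config import QCConfig
from eegqc.preprocessing import EpochArray
from eegqc.recording_io import Recording
from eegqc.spectral import welch_psd


@dataclass
class ChannelQCResult:
    """Per-channel flags and raw criterion scores for one method."""

    method: str
    per_criterion: dict[str, np.ndarray]  # criterion -> bool vector (M,)
    scores: dict[str, np.ndarray]         # criterion -> float vector (M,)
    meta: dict = field(default_factory=dict)

    @property
    def bad(self) -> np.ndarray:
        flags = np.column_stack(list(self.per_criterion.values()))
        return flags.any(axis=1)

    @property
    def n_items(self) -> int:
        return len(next(iter(self.per_criterion.values())))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "bad": self.bad.astype(int).tolist(),
            "per_criterion": {k: v.astype(int).tolist()
                              for k, v in self.per_criterion.items()},
            "scores": {k: [None if not np.isfinite(x) else float(x) for x in v]
                       for k, v in self.scores.items()},
            "meta": self.meta,
        }


class EpochQCResult(ChannelQCResult):
    """Same layout as :class:`ChannelQCResult`, indexed by epoch."""


def zscore(values: np.ndarray) -> np.ndarray:
    """Standard Z-score with sample standard deviation (ddof=1).

    A zero or undefined spread yields all-zero scores: identical
    entries are not evidence of badness.  NaNs are ignored when
    estimating the mean and spread and map to NaN scores.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("zscore needs a 1-D vector of length >= 2")
    finite = np.isfinite(v)
    if finite.sum() < 2:
        return np.zeros_like(v)
    sd = np.std(v[finite], ddof=1)
    if sd == 0 or not np.isfinite(sd):
        out = np.zeros_like(v)
        out[~finite] = np.nan
        return out
    out = (v - np.mean(v[finite])) / sd
    return out


def hurst_exponent(series: np.ndarray, min_block: int = 16,
                   max_block_frac: float = 0.25) -> float:
    """Hurst exponent by classical rescaled-range (R/S) analysis.

    The series is partitioned into non-overlapping blocks of dyadic
    sizes from ``min_block`` to ``max_block_frac * len``; in each block
    the range of the cumulative mean-deviation is divided by the block
    sample standard deviation, R/S is averaged over blocks, and the
    slope of log(R/S) against log(block size) estimates H.  White noise
    gives H near 0.5 (small-sample R/S is biased slightly upward);
    persistent signals approach 1.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 8 * min_block:
        raise ValueError(
            f"series of length {x.size} too short for R/S analysis "
            f"(need >= {8 * min_block})")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no defined Hurst exponent")
    max_block = int(x.size * max_block_frac)
    sizes = []
    n = min_block
    while n <= max_block:
        sizes.append(n)
        n *= 2
    log_n, log_rs = [], []
    for n in sizes:
        k = x.size // n
        blocks = x[:k * n].reshape(k, n)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        cum = np.cumsum(dev, axis=1)
        r = cum.max(axis=1) - cum.min(axis=1)
        s = blocks.std(axis=1, ddof=1)
        ok = s > 0
        if not ok.any():
            continue
        log_n.append(np.log(n))
        log_rs.append(np.log(np.mean(r[ok] / s[ok])))
    if len(log_n) < 2:
        raise ValueError("too few usable block sizes for R/S regression")
    slope, _ = np.polyfit(log_n, log_rs, 1)
    return float(slope)


def _mean_abs_correlation(data: np.ndarray) -> np.ndarray:
    """Mean |Pearson r| of each channel against all others; constant
    channels get correlation 0 (maximally suspicious)."""
    m = data.shape[0]
    sd = data.std(axis=1)
    ok = sd > 0
    corr = np.zeros((m, m))
    if ok.sum() >= 2:
        corr[np.ix_(ok, ok)] = np.corrcoef(data[ok])
    np.fill_diagonal(corr, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.abs(corr), axis=1)


def faster_bad_channels(rec: Recording, cfg: QCConfig | None = None) -> ChannelQCResult:
    """FASTER bad-channel detection on a high-pass-filtered recording.

    Four per-channel statistics — mean absolute pairwise correlation,
    variance, Hurst exponent, and mean 48-62 Hz band power — are each
    Z-scored across channels; a channel is flagged when any |Z|
    exceeds the threshold (default 3).
    """
    cfg = cfg or QCConfig()
    if rec.n_channels < 4:
        raise ValueError("need >= 4 channels for cross-channel Z-scores")
    x = rec.data
    stats = {
        "correlation": _mean_abs_correlation(x),
        "variance": x.var(axis=1, ddof=1),
        # a constant channel has no defined Hurst exponent; it is left
        # out of the standardization (the correlation and variance
        # criteria still see it)
        "hurst": np.array([np.nan if np.ptp(ch) == 0 else
                           hurst_exponent(ch, cfg.hurst_min_block,
                                          cfg.hurst_max_block_frac)
                           for ch in x]),
        "powerline": _band_power(rec, cfg),
    }
    per_criterion, scores = {}, {}
    for name, stat in stats.items():
        z = zscore(stat)
        scores[name] = z
        per_criterion[name] = np.abs(z) > cfg.faster_z
    return ChannelQCResult(
        method="FASTER", per_criterion=per_criterion, scores=scores,
        meta={"threshold": cfg.faster_z, "directionality": "two-sided |Z|",
              "correlation_statistic": "mean |Pearson r| vs all other channels, full recording",
              "powerline_band_hz": list(cfg.powerline_band_hz)})


def _band_power(rec: Recording, cfg: QCConfig) -> np.ndarray:
    lo, hi = cfg.powerline_band_hz
    psd = welch_psd(rec, window_s=cfg.welch_window_s, overlap=cfg.welch_overlap)
    band = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not band.any():
        raise ValueError(f"no spectral bins inside {lo}-{hi} Hz at fs={rec.fs}")
    return psd.power[:, band].mean(axis=1)


def faster_bad_epochs(ep: EpochArray, cfg: QCConfig | None = None) -> EpochQCResult:
    """FASTER bad-epoch detection.

    Per epoch: amplitude range (max - min) and variance, each averaged
    across channels; and the deviation parameter — the epoch mean of
    each channel minus that channel's average epoch mean, averaged
    across channels.  Each N-vector is Z-scored over epochs and any
    |Z| above the threshold flags the epoch.
    """
    cfg = cfg or QCConfig()
    if ep.n_epochs < 4:
        raise ValueError("need >= 4 epochs for cross-epoch Z-scores")
    x = ep.data  # (N, M, S)
    rng = x.max(axis=2) - x.min(axis=2)          # (N, M)
    var = x.var(axis=2, ddof=1)                  # (N, M)
    ep_means = x.mean(axis=2)                    # (N, M)
    dev = ep_means - ep_means.mean(axis=0)       # deviation from channel mean
    stats = {
        "amplitude_range": rng.mean(axis=1),
        "variance": var.mean(axis=1),
        "deviation": dev.mean(axis=1),
    }
    per_criterion, scores = {}, {}
    for name, stat in stats.items():
        z = zscore(stat)
        scores[name] = z
        per_criterion[name] = np.abs(z) > cfg.faster_z
    return EpochQCResult(
        method="FASTER", per_criterion=per_criterion, scores=scores,
        meta={"threshold": cfg.faster_z, "directionality": "two-sided |Z|",
              "deviation_reference": "channel-wise mean of epoch means"})
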