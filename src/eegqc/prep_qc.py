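"""PREP-style artifact detection with robust statistics.

The PREP criteria replace mean/SD standardization with median/IQR:
the robust standard deviation is the interquartile range times 0.7413
(the reciprocal of twice the standard-normal upper quartile, which
makes the IQR-based scale agree with the SD under Gaussianity), and
the robust Z-score is (value - median) / robust SD, thresholded at 5.

Channel criteria (four):

* flat/NaN — any NaN, or peak-to-peak amplitude below 1e-15 uV for
  the whole channel or in more than 1% of 2 s windows;
* amplitude — per-channel robust SD of the full signal, robust-Z
  standardized across channels, |Z| > 5;
* correlation — per 2 s window each channel's best absolute
  correlation with any other channel; flagged when it falls below 0.4
  in more than 1% of windows;
* noisiness — ratio of high- to low-frequency robust amplitude after
  a 50 Hz FIR split, robust Z > 5 (one-sided: only a high ratio
  indicates noise).

The epoch criterion standardizes both the per-epoch median (location)
and per-epoch robust SD (scale) across each channel's epochs; an epoch
is bad when the larger |robust Z| of the two exceeds 5 in any channel.
Both components are exposed separately in the result.
"""

from __future__ import annotations

import numpy as np

from eegqc.config import QCConfig
from eegqc.faster_qc import ChannelQCResult, EpochQCResult
from eegqc.preprocessing import EpochArray, split_bands
from eegqc.recording_io import Recording


def robust_std(values: np.ndarray, iqr_to_std: float = 0.7413) -> float:
    """(Q3 - Q1) * 0.7413 with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise ValueError("robust_std needs >= 4 values")
    q1, q3 = np.percentile(v, [25, 75])
    return float((q3 - q1) * iqr_to_std)


def robust_zscore(values: np.ndarray, iqr_to_std: float = 0.7413) -> np.ndarray:
    """(v - median) / robust_std(v); all zeros when the robust SD
    vanishes (identical values are not evidence of badness)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise ValueError("robust_zscore needs a 1-D vector of length >= 4")
    s = robust_std(v, iqr_to_std)
    if s == 0 or not np.isfinite(s):
        return np.zeros_like(v)
    return (v - np.median(v)) / s


def _masked_robust_z(stat: np.ndarray, good: np.ndarray,
                     iqr_to_std: float) -> np.ndarray:
    """Robust-Z of ``stat`` computed over the good channels only; bad
    channels receive NaN scores and never flag this criterion."""
    z = np.full(stat.shape, np.nan)
    if good.sum() >= 4:
        z[good] = robust_zscore(stat[good], iqr_to_std)
    elif good.sum() > 0:
        z[good] = 0.0
    return z


def _window_view(data: np.ndarray, win: int) -> np.ndarray:
    """(M, T) -> (n_windows, M, win), trailing partial window dropped."""
    m, t = data.shape
    k = t // win
    if k == 0:
        raise ValueError(f"signal shorter than one {win}-sample window")
    return data[:, :k * win].reshape(m, k, win).transpose(1, 0, 2)


def _flat_or_nan(data: np.ndarray, win: int, flat_thresh: float,
                 window_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Criterion (a): NaN anywhere, globally flat, or flat in more
    than ``window_frac`` of windows.  Returns (flags, score) where the
    score is the fraction of flat windows."""
    has_nan = np.isnan(data).any(axis=1)
    clean = np.nan_to_num(data, nan=0.0)
    global_flat = np.ptp(clean, axis=1) < flat_thresh
    windows = _window_view(clean, win)                    # (K, M, win)
    flat_win = np.ptp(windows, axis=2) < flat_thresh      # (K, M)
    frac_flat = flat_win.mean(axis=0)
    return has_nan | global_flat | (frac_flat > window_frac), frac_flat


def _windowed_max_correlation(data: np.ndarray, win: int,
                              good: np.ndarray) -> np.ndarray:
    """Per window, each channel's maximum |Pearson r| against any
    other good channel; returns the (K, M) matrix (NaN outside
    ``good`` or when a window is constant)."""
    windows = _window_view(data, win)
    k, m, _ = windows.shape
    out = np.full((k, m), np.nan)
    idx = np.flatnonzero(good)
    if idx.size < 2:
        return out
    for w in range(k):
        seg = windows[w][idx]
        sd = seg.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2:
            out[w, idx[ok]] = 0.0
            continue
        c = np.corrcoef(seg[ok])
        np.fill_diagonal(c, np.nan)
        best = np.nanmax(np.abs(c), axis=1)
        out[w, idx[ok]] = best
        out[w, idx[~ok]] = 0.0
    return out


def prep_bad_channels(rec: Recording, cfg: QCConfig | None = None) -> ChannelQCResult:
    """PREP bad-channel detection on a high-pass-filtered recording.

    Channels flagged flat/NaN are excluded from the cross-channel
    standardization of the other criteria (and as correlation
    partners), so one dead channel cannot mask another.
    """
    cfg = cfg or QCConfig()
    m = rec.n_channels
    if m < 4:
        raise ValueError("need >= 4 channels for cross-channel robust Z-scores")
    win = int(round(cfg.epoch_len_s * rec.fs))
    if rec.n_samples < win:
        raise ValueError("recording shorter than one correlation window")
    x = rec.data

    flat_flags, flat_score = _flat_or_nan(
        x, win, cfg.flat_thresh_uv, cfg.prep_window_frac)
    good = ~flat_flags
    x_clean = np.nan_to_num(x, nan=0.0)

    # (b) amplitude: robust SD of the full signal, |robust Z| across channels
    amp = np.array([robust_std(ch, cfg.iqr_to_std) for ch in x_clean])
    amp_z = _masked_robust_z(amp, good, cfg.iqr_to_std)
    with np.errstate(invalid="ignore"):
        amp_flags = np.abs(amp_z) > cfg.prep_robust_z
    amp_flags &= good

    # (c) correlation: best |r| per 2 s window below threshold in >1% of windows
    best_corr = _windowed_max_correlation(x_clean, win, good)
    with np.errstate(invalid="ignore"):
        low = best_corr < cfg.prep_corr_thresh
    frac_low = np.where(good, np.nanmean(
        np.where(np.isnan(best_corr), 0.0, low), axis=0), np.nan)
    corr_flags = good & (frac_low > cfg.prep_window_frac)

    # (d) noisiness: high/low-band robust-amplitude ratio, one-sided robust Z
    low_rec, high_rec = split_bands(rec.copy_with(data=x_clean), cfg.split_hz)
    low_amp = np.array([robust_std(ch, cfg.iqr_to_std) for ch in low_rec.data])
    high_amp = np.array([robust_std(ch, cfg.iqr_to_std) for ch in high_rec.data])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(low_amp > 0, high_amp / low_amp, np.inf)
    ratio_z = _masked_robust_z(ratio, good, cfg.iqr_to_std)
    with np.errstate(invalid="ignore"):
        noise_flags = ratio_z > cfg.prep_robust_z
    noise_flags &= good

    return ChannelQCResult(
        method="PREP",
        per_criterion={"flat": flat_flags, "amplitude": amp_flags,
                       "correlation": corr_flags, "noisiness": noise_flags},
        scores={"flat": flat_score, "amplitude": amp_z,
                "correlation": frac_low, "noisiness": ratio_z},
        meta={"threshold": cfg.prep_robust_z,
              "window_s": cfg.epoch_len_s,
              "amplitude_statistic": "robust SD of full signal, two-sided robust Z",
              "noisiness_statistic": "high/low robust-amplitude ratio at "
                                     f"{cfg.split_hz} Hz, one-sided robust Z",
              "flat_thresh_uv": cfg.flat_thresh_uv,
              "corr_thresh": cfg.prep_corr_thresh,
              "window_frac": cfg.prep_window_frac})


def prep_bad_epochs(ep: EpochArray, cfg: QCConfig | None = None) -> EpochQCResult:
    """Modified-PREP bad-epoch detection.

    For every channel and epoch the median and the robust SD of the
    epoch's samples are computed; each statistic is robust-Z
    standardized across the channel's epochs, and the epoch-channel
    score is the larger |robust Z| of the two.  An epoch is bad when
    its maximum score over channels exceeds the threshold (default 5).
    """
    cfg = cfg or QCConfig()
    n, m, s = ep.data.shape
    if n < 4:
        raise ValueError("need >= 4 epochs for cross-epoch robust Z-scores")
    med = np.median(ep.data, axis=2)                       # (N, M)
    q1, q3 = np.percentile(ep.data, [25, 75], axis=2)
    rsd = (q3 - q1) * cfg.iqr_to_std                       # (N, M)
    z_med = np.column_stack(
        [robust_zscore(med[:, j], cfg.iqr_to_std) for j in range(m)])
    z_rsd = np.column_stack(
        [robust_zscore(rsd[:, j], cfg.iqr_to_std) for j in range(m)])
    loc_flags = (np.abs(z_med) > cfg.prep_robust_z).any(axis=1)
    scale_flags = (np.abs(z_rsd) > cfg.prep_robust_z).any(axis=1)
    score = np.maximum(np.abs(z_med), np.abs(z_rsd)).max(axis=1)
    return EpochQCResult(
        method="PREP",
        per_criterion={"location": loc_flags, "scale": scale_flags},
        scores={"location": np.abs(z_med).max(axis=1),
                "scale": np.abs(z_rsd).max(axis=1),
                "max_robust_z": score},
        meta={"threshold": cfg.prep_robust_z,
              "statistics": "per-epoch median and robust SD, each robust-Z "
                            "standardized across epochs per channel; "
                            "max |Z| over channels"})
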