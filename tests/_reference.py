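"""Naive, loop-based reference implementations of the FASTER and PREP
flagging pipelines.

These re-derive the criterion aggregation and thresholding logic with
explicit Python loops, independently of the vectorized package code,
and are used to cross-check flags on small inputs.  Scalar primitives
with a single canonical definition (Welch PSD via scipy, the Hurst
estimator, numpy percentiles) are shared; everything about how
statistics are assembled, standardized and thresholded is re-written
here from the method definitions.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as _signal

from eegqc.faster_qc import hurst_exponent
from eegqc.preprocessing import split_bands


def ref_zscore(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    if sd == 0:
        return [0.0] * n
    return [(v - mean) / sd for v in values]


def ref_robust_std(values):
    q1, q3 = np.percentile(list(values), [25, 75])
    return (q3 - q1) * 0.7413


def ref_robust_zscore(values):
    values = list(values)
    med = float(np.median(values))
    s = ref_robust_std(values)
    if s == 0:
        return [0.0] * len(values)
    return [(v - med) / s for v in values]


def ref_faster_bad_epochs(data, thresh=3.0):
    """data: (N, M, S).  Returns boolean bad-epoch list."""
    n, m, s = data.shape
    ranges, variances, epoch_means = [], [], []
    for i in range(n):
        r = [float(data[i, j].max() - data[i, j].min()) for j in range(m)]
        v = [float(np.var(data[i, j], ddof=1)) for j in range(m)]
        mu = [float(data[i, j].mean()) for j in range(m)]
        ranges.append(sum(r) / m)
        variances.append(sum(v) / m)
        epoch_means.append(mu)
    channel_mean = [sum(epoch_means[i][j] for i in range(n)) / n
                    for j in range(m)]
    deviation = [sum(epoch_means[i][j] - channel_mean[j] for j in range(m)) / m
                 for i in range(n)]
    bad = [False] * n
    for stat in (ranges, variances, deviation):
        for i, z in enumerate(ref_zscore(stat)):
            if abs(z) > thresh:
                bad[i] = True
    return bad


def ref_faster_bad_channels(rec, cfg):
    """Recording (already high-passed) -> boolean bad-channel list."""
    x = rec.data
    m = x.shape[0]
    mean_corr = []
    for i in range(m):
        cs = []
        for j in range(m):
            if j == i:
                continue
            r = np.corrcoef(x[i], x[j])[0, 1]
            cs.append(abs(r))
        mean_corr.append(sum(cs) / len(cs))
    variances = [float(np.var(x[i], ddof=1)) for i in range(m)]
    hursts = [hurst_exponent(x[i], cfg.hurst_min_block, cfg.hurst_max_block_frac)
              for i in range(m)]
    nps = int(round(cfg.welch_window_s * rec.fs))
    band_power = []
    for i in range(m):
        f, p = _signal.welch(x[i], fs=rec.fs, window="hann", nperseg=nps,
                             noverlap=int(round(cfg.welch_overlap * nps)),
                             scaling="density")
        sel = (f >= cfg.powerline_band_hz[0]) & (f <= cfg.powerline_band_hz[1])
        band_power.append(float(p[sel].mean()))
    bad = [False] * m
    for stat in (mean_corr, variances, hursts, band_power):
        for i, z in enumerate(ref_zscore(stat)):
            if abs(z) > cfg.faster_z:
                bad[i] = True
    return bad


def ref_prep_bad_epochs(data, thresh=5.0):
    """data: (N, M, S) -> boolean bad-epoch list: per-channel robust-Z
    of the per-epoch median and robust SD, max |Z| over channels."""
    n, m, s = data.shape
    bad = [False] * n
    for j in range(m):
        med = [float(np.median(data[i, j])) for i in range(n)]
        rsd = [ref_robust_std(data[i, j]) for i in range(n)]
        z_med = ref_robust_zscore(med)
        z_rsd = ref_robust_zscore(rsd)
        for i in range(n):
            if max(abs(z_med[i]), abs(z_rsd[i])) > thresh:
                bad[i] = True
    return bad


def ref_prep_bad_channels(rec, cfg):
    """Recording (already high-passed) -> boolean bad-channel list."""
    x = rec.data
    m, t = x.shape
    win = int(round(cfg.epoch_len_s * rec.fs))
    k = t // win

    flat = []
    for i in range(m):
        ch = x[i]
        if np.isnan(ch).any():
            flat.append(True)
            continue
        if ch.max() - ch.min() < cfg.flat_thresh_uv:
            flat.append(True)
            continue
        nflat = sum(
            1 for w in range(k)
            if np.ptp(ch[w * win:(w + 1) * win]) < cfg.flat_thresh_uv)
        flat.append(nflat / k > cfg.prep_window_frac)
    good = [i for i in range(m) if not flat[i]]

    bad = list(flat)
    clean = np.nan_to_num(x, nan=0.0)

    if len(good) >= 4:
        amp = [ref_robust_std(clean[i]) for i in good]
        for i, z in zip(good, ref_robust_zscore(amp)):
            if abs(z) > cfg.prep_robust_z:
                bad[i] = True

    for i in good:
        n_low = 0
        for w in range(k):
            best = 0.0
            seg_i = clean[i, w * win:(w + 1) * win]
            if seg_i.std() == 0:
                n_low += 1
                continue
            for j in good:
                if j == i:
                    continue
                seg_j = clean[j, w * win:(w + 1) * win]
                if seg_j.std() == 0:
                    continue
                best = max(best, abs(np.corrcoef(seg_i, seg_j)[0, 1]))
            if best < cfg.prep_corr_thresh:
                n_low += 1
        if n_low / k > cfg.prep_window_frac:
            bad[i] = True

    low, high = split_bands(rec.copy_with(data=clean), cfg.split_hz)
    if len(good) >= 4:
        ratio = [ref_robust_std(high.data[i]) / ref_robust_std(low.data[i])
                 for i in good]
        for i, z in zip(good, ref_robust_zscore(ratio)):
            if z > cfg.prep_robust_z:
                bad[i] = True
    return bad
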