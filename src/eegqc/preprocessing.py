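"""Filtering and epoching applied before any quality detection.

All filters are zero-phase FIR (Hamming-windowed design, applied
forward-backward), so channel and epoch criteria computed on the
filtered signal stay sample-aligned with the raw recording.  Epochs are
contiguous, non-overlapping, and a trailing partial epoch is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from eegqc.recording_io import Recording


class TooShortError(ValueError):
    """Recording shorter than the filter transient or one epoch."""


@dataclass
class EpochArray:
    """A recording cut into fixed-length epochs.

    ``data`` has shape (N epochs, M channels, S samples) with
    S = round(epoch_len_s * fs); concatenating the epochs in order
    reproduces the first N*S samples of the source recording.
    """

    data: np.ndarray
    fs: float
    epoch_len_s: float
    source: Recording | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochArray.data must be 3-D (epochs x channels x samples)")
        if self.data.shape[2] != round(self.epoch_len_s * self.fs):
            raise ValueError("epoch sample count inconsistent with epoch_len_s * fs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def _hamming_fir(fs: float, cutoff_hz: float, width_hz: float,
                 pass_zero) -> np.ndarray:
    """Design a Hamming-window FIR with the requested transition width.

    The Hamming window needs roughly 3.3/width normalized taps for its
    transition band; the count is rounded up to an odd number so the
    filter is type I (no notch at Nyquist, exact null at DC for the
    high-pass case).
    """
    ntaps = int(np.ceil(3.3 * fs / width_hz))
    ntaps += 1 - ntaps % 2
    taps = signal.firwin(ntaps, cutoff_hz, window="hamming",
                         pass_zero=pass_zero, fs=fs)
    if not pass_zero:
        # force an exact null at DC so constants are fully rejected;
        # the broadband shift is ~taps.sum()/ntaps, far below passband ripple
        taps -= taps.sum() / ntaps
    return taps


def _filtfilt(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    padlen = len(taps)
    if data.shape[-1] <= padlen:
        raise TooShortError(
            f"recording of {data.shape[-1]} samples is shorter than the "
            f"filter transient ({padlen} samples)")
    # reflect-padding of one filter length keeps startup transients out
    # of the first epoch
    return signal.filtfilt(taps, [1.0], data, axis=-1,
                           padtype="even", padlen=padlen)


def highpass(rec: Recording, cutoff_hz: float = 0.5) -> Recording:
    """Zero-phase FIR high-pass; transition band <= cutoff (so a
    0.5 Hz cutoff has its stopband edge near 0.25 Hz)."""
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, fs/2)")
    taps = _hamming_fir(rec.fs, cutoff_hz, width_hz=cutoff_hz, pass_zero=False)
    return rec.copy_with(data=_filtfilt(taps, rec.data))


def split_bands(rec: Recording, split_hz: float = 50.0,
                width_hz: float = 5.0) -> tuple[Recording, Recording]:
    """Separate low- and high-frequency components with a zero-phase
    FIR low-pass at ``split_hz``; high = original - low, so the two
    parts sum back to the input exactly."""
    if not 0 < split_hz < rec.fs / 2:
        raise ValueError(f"split frequency {split_hz} Hz outside (0, fs/2)")
    taps = _hamming_fir(rec.fs, split_hz, width_hz=width_hz, pass_zero=True)
    low = _filtfilt(taps, rec.data)
    return rec.copy_with(data=low), rec.copy_with(data=rec.data - low)


def epoch(rec: Recording, epoch_len_s: float = 2.0) -> EpochArray:
    """Cut a recording into contiguous non-overlapping epochs,
    discarding the trailing partial epoch."""
    s = int(round(epoch_len_s * rec.fs))
    m, t = rec.data.shape
    if t < s:
        raise TooShortError(
            f"recording of {t / rec.fs:.3g} s is shorter than one "
            f"{epoch_len_s} s epoch")
    n = t // s
    data = rec.data[:, :n * s].reshape(m, n, s).transpose(1, 0, 2).copy()
    return EpochArray(data=data, fs=rec.fs, epoch_len_s=epoch_len_s, source=rec)


def concatenate(ep: EpochArray) -> np.ndarray:
    """Inverse of :func:`epoch` up to the discarded tail: returns the
    (M, N*S) array of epochs laid end to end."""
    n, m, s = ep.data.shape
    return ep.data.transpose(1, 0, 2).reshape(m, n * s)
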