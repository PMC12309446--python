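"""Numeric constants of the quality-control pipeline.

Every threshold used by the FASTER and PREP criteria, the filter
cutoffs, the spectral-analysis settings and the bootstrap iteration
count live here, so a deployment can adjust them in one place (or via a
YAML file) and every run records which values it used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml


@dataclass(frozen=True)
class QCConfig:
    """Tunable parameters of the QC pipeline.

    Attributes
    ----------
    epoch_len_s : float
        Epoch length in seconds for epoch-level criteria.
    highpass_hz : float
        High-pass cutoff applied before any detection.
    split_hz : float
        Low-pass cutoff of the FIR filter separating low- and
        high-frequency components for the PREP noisiness criterion.
    faster_z : float
        |Z| threshold of every FASTER criterion.
    prep_robust_z : float
        Robust-Z threshold of the PREP amplitude, noisiness and epoch
        criteria.
    prep_corr_thresh : float
        Windowed-correlation floor below which a window counts against
        a channel.
    prep_window_frac : float
        Fraction of bad 2 s windows above which the correlation or
        flatness criterion flags a channel.
    flat_thresh_uv : float
        Peak-to-peak amplitude (microvolts) below which a signal is
        considered flat.
    powerline_band_hz : tuple
        Band whose mean power feeds the FASTER powerline criterion;
        48-62 Hz covers both 50 and 60 Hz mains.
    alpha_band_hz : tuple
        Band searched for the peak alpha frequency.
    welch_window_s, welch_overlap : float
        Welch periodogram window length (seconds) and overlap fraction.
    bootstrap_iters : int
        Subsample-and-test iterations of the bootstrap group comparison.
    iqr_to_std : float
        Factor converting an interquartile range to a standard
        deviation under Gaussianity (1 / (2 * Phi^-1(3/4)) = 0.7413).
    hurst_min_block, hurst_max_block_frac : int, float
        Dyadic block-size range of the rescaled-range Hurst estimator.
    """

    epoch_len_s: float = 2.0
    highpass_hz: float = 0.5
    split_hz: float = 50.0
    faster_z: float = 3.0
    prep_robust_z: float = 5.0
    prep_corr_thresh: float = 0.4
    prep_window_frac: float = 0.01
    flat_thresh_uv: float = 1e-15
    powerline_band_hz: tuple[float, float] = (48.0, 62.0)
    alpha_band_hz: tuple[float, float] = (7.0, 12.0)
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    bootstrap_iters: int = 50
    iqr_to_std: float = 0.7413
    hurst_min_block: int = 16
    hurst_max_block_frac: float = 0.25

    def __post_init__(self) -> None:
        positive = (
            "epoch_len_s", "highpass_hz", "split_hz", "faster_z",
            "prep_robust_z", "prep_corr_thresh", "prep_window_frac",
            "flat_thresh_uv", "welch_window_s", "iqr_to_std",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"QCConfig.{name} must be strictly positive")
        for name in ("powerline_band_hz", "alpha_band_hz"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"QCConfig.{name} must satisfy 0 < lo < hi")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("QCConfig.welch_overlap must be in [0, 1)")
        if self.bootstrap_iters < 1:
            raise ValueError("QCConfig.bootstrap_iters must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["powerline_band_hz"] = list(self.powerline_band_hz)
        d["alpha_band_hz"] = list(self.alpha_band_hz)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "QCConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("powerline_band_hz", "alpha_band_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
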