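"""Synthetic field-like EEG with ground-truth artifact labels.

The generator emulates the study conditions of the field protocol —
3-minute, 16-channel, 256 Hz resting recordings — so that every
pipeline stage can be exercised and scored without real data:

* background: a handful of shared pink-noise (1/f^beta) sources mixed
  into all channels through a common mixing matrix, plus a small
  per-channel white-noise floor.  The shared sources give clean
  channels the strong pairwise correlation real EEG shows (well above
  the 0.4 windowed-correlation floor of the PREP criterion);
* an alpha oscillation: a sinusoid at a controllable peak frequency
  with a slow amplitude envelope, weighted toward posterior channels;
* optional 50/60 Hz line contamination on a channel subset;
* injectable artifacts with ground-truth labels: flat channel,
  high-variance channel, uncorrelated channel, transient
  high-amplitude burst epochs, and frontal eyeblink deflections.

Artifact magnitudes in real field data are unreported; the defaults
here are calibration choices (documented in the package methods note),
not measured facts.

The module also provides an exact fractional-Gaussian-noise generator
(circulant embedding), used as an independent oracle for the Hurst
estimator.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from eegqc.recording_io import Recording, SessionMeta, load_montage

_POSTERIOR = {"O1", "O2", "P7", "P3", "P4", "P8"}
_CENTRAL = {"C3", "C4", "T7", "T8"}
_FRONTAL = {"Fp1", "Fp2", "F7", "F3", "F4", "F8"}

ARTIFACT_KINDS = ("flat_channel", "noisy_channel", "uncorrelated_channel",
                  "burst_epoch", "blink")


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected artifact.

    ``channel`` indexes the affected channel (channel-level kinds and
    ``burst_epoch``); ``epochs`` lists affected 2 s epoch indices
    (``burst_epoch`` and ``blink``).  ``magnitude`` scales the
    artifact relative to the clean channel's amplitude.
    """

    kind: str
    channel: int | None = None
    epochs: tuple[int, ...] = ()
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}; "
                             f"expected one of {ARTIFACT_KINDS}")


@dataclass(frozen=True)
class AlphaSpec:
    """Alpha oscillation: peak frequency (Hz, within 7-12), amplitude
    of the posterior-channel sinusoid (uV) and the posterior/central/
    frontal weighting."""

    peak_hz: float = 10.0
    amplitude_uv: float = 12.0
    bandwidth_hz: float = 0.2     # slow-envelope modulation bandwidth
    posterior_weight: float = 1.0
    central_weight: float = 0.7
    frontal_weight: float = 0.4


@dataclass(frozen=True)
class LineNoiseSpec:
    """Mains contamination: 50 or 60 Hz sinusoid on a channel subset
    (empty tuple = all channels)."""

    freq_hz: float = 50.0
    amplitude_uv: float = 0.0
    channels: tuple[int, ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic recording.

    Defaults are the field-protocol conditions: 16 channels of the
    10-20 system, 256 Hz, 3 minutes, a 1/f background of ~20 uV and a
    10 Hz posterior alpha rhythm.
    """

    n_channels: int = 16
    fs: float = 256.0
    duration_s: float = 180.0
    background_exponent: float = 1.0
    background_amplitude_uv: float = 20.0
    noise_floor_frac: float = 0.05
    n_sources: int = 4
    alpha: AlphaSpec = field(default_factory=AlphaSpec)
    line_noise: LineNoiseSpec = field(default_factory=LineNoiseSpec)
    artifacts: tuple[ArtifactSpec, ...] = ()
    epoch_len_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_channels < 1:
            errors.append("n_channels must be >= 1")
        if self.fs <= 0:
            errors.append("fs must be positive")
        if self.duration_s <= 0:
            errors.append("duration_s must be positive")
        if self.background_amplitude_uv < 0:
            errors.append("background_amplitude_uv must be >= 0")
        if self.alpha.amplitude_uv < 0:
            errors.append("alpha amplitude must be >= 0")
        if self.alpha.amplitude_uv > 0 and not 7 <= self.alpha.peak_hz <= 12:
            errors.append(f"alpha peak {self.alpha.peak_hz} Hz outside [7, 12]")
        if self.line_noise.amplitude_uv < 0:
            errors.append("line-noise amplitude must be >= 0")
        n_ep = int(self.duration_s // self.epoch_len_s)
        for a in self.artifacts:
            if a.channel is not None and not 0 <= a.channel < self.n_channels:
                errors.append(f"artifact channel {a.channel} out of range")
            for e in a.epochs:
                if not 0 <= e < n_ep:
                    errors.append(f"artifact epoch {e} out of range (N={n_ep})")
        if errors:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(errors))

    def to_yaml(self, path: str) -> None:
        d = {
            "n_channels": self.n_channels, "fs": self.fs,
            "duration_s": self.duration_s,
            "background_exponent": self.background_exponent,
            "background_amplitude_uv": self.background_amplitude_uv,
            "noise_floor_frac": self.noise_floor_frac,
            "n_sources": self.n_sources,
            "alpha": vars(self.alpha).copy(),
            "line_noise": {**vars(self.line_noise),
                           "channels": list(self.line_noise.channels)},
            "artifacts": [{"kind": a.kind, "channel": a.channel,
                           "epochs": list(a.epochs), "magnitude": a.magnitude}
                          for a in self.artifacts],
            "epoch_len_s": self.epoch_len_s, "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["alpha"] = AlphaSpec(**d.get("alpha", {}))
        ln = d.get("line_noise", {})
        ln["channels"] = tuple(ln.get("channels", ()))
        d["line_noise"] = LineNoiseSpec(**ln)
        d["artifacts"] = tuple(
            ArtifactSpec(kind=a["kind"], channel=a.get("channel"),
                         epochs=tuple(a.get("epochs", ())),
                         magnitude=a.get("magnitude"))
            for a in d.get("artifacts", []))
        return cls(**d)


@dataclass
class SyntheticGroundTruth:
    """Injected-artifact labels for scoring detector recovery."""

    bad_channels: dict[int, str]          # channel index -> artifact kind
    bad_epochs: dict[int, str]            # epoch index -> artifact kind
    true_paf: float | None

    def to_dict(self) -> dict:
        return {"bad_channels": {str(k): v for k, v in self.bad_channels.items()},
                "bad_epochs": {str(k): v for k, v in self.bad_epochs.items()},
                "true_paf": self.true_paf}


# ---------------------------------------------------------------------------
# Noise primitives

def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise by spectral synthesis (shaping
    the rFFT of white noise by f^(-exponent/2), zero DC)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def fractional_gaussian_noise(h: float, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding
    (Davies-Harte).  H=0.5 is white noise; H>0.5 persistent.

    Used as the independent simulation oracle for the rescaled-range
    Hurst estimator.
    """
    if not 0 < h < 1:
        raise ValueError("Hurst parameter must be in (0, 1)")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h)
                   + np.abs(k - 1) ** (2 * h))
    row = np.concatenate([gamma, gamma[-2:0:-1]])          # length 2n
    eig = np.fft.fft(row).real
    eig[eig < 0] = 0.0                                     # clip tiny negatives
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    coeff = np.sqrt(eig / (2 * m)) * z
    return np.fft.fft(coeff).real[:n] * np.sqrt(2.0)


def _slow_envelope(n: int, fs: float, bandwidth_hz: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Positive amplitude envelope varying below ``bandwidth_hz`` so
    the spectral peak of an enveloped sinusoid stays on its carrier
    bin at 0.5 Hz resolution."""
    t = np.arange(n) / fs
    f_mod = min(bandwidth_hz / 2.0, 0.2)
    phase = rng.uniform(0, 2 * np.pi)
    return 1.0 + 0.3 * np.sin(2 * np.pi * f_mod * t + phase)


# ---------------------------------------------------------------------------
# Recording generation

def _alpha_weights(labels: list[str], alpha: AlphaSpec) -> np.ndarray:
    """Alpha amplitude per channel: strongest posterior, weakest
    frontal.  Channels beyond the named montage cycle through the same
    three weights so larger simulated caps keep a head-like
    heterogeneity."""
    cycle = (alpha.posterior_weight, alpha.central_weight,
             alpha.frontal_weight)
    w = np.empty(len(labels))
    for i, lb in enumerate(labels):
        if lb in _POSTERIOR:
            w[i] = alpha.posterior_weight
        elif lb in _FRONTAL:
            w[i] = alpha.frontal_weight
        elif lb in _CENTRAL:
            w[i] = alpha.central_weight
        else:
            w[i] = cycle[i % 3]
    return w


def _default_labels(n_channels: int) -> list[str]:
    std = load_montage()["standard"]
    if n_channels <= len(std):
        return std[:n_channels]
    return std + [f"EXT{i}" for i in range(n_channels - len(std))]


def _burst_shape(s: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Hann-windowed burst covering ~40% of an epoch at a random
    offset; unit peak amplitude."""
    width = max(8, int(0.4 * s))
    start = rng.integers(0, s - width + 1)
    out = np.zeros(s)
    out[start:start + width] = np.hanning(width)
    return out


def _blink_shape(s: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Biphasic low-frequency (~0.5-2 Hz content) eyeblink deflection:
    the derivative of a Gaussian, ~0.4 s wide, unit peak."""
    width = int(0.4 * fs)
    start = rng.integers(0, max(1, s - width))
    t = np.linspace(-3, 3, width)
    shape = -t * np.exp(-t ** 2 / 2)
    shape /= np.abs(shape).max()
    out = np.zeros(s)
    out[start:start + width] = shape
    return out


def generate_recording(spec: SyntheticSpec,
                       condition: str = "EC",
                       session: SessionMeta | None = None
                       ) -> tuple[Recording, SyntheticGroundTruth]:
    """Generate one synthetic recording plus its ground truth.

    Fully deterministic given the spec (including its seed).  Clean
    channels share pink-noise sources, so their pairwise windowed
    correlation stays far above the PREP 0.4 floor; injected artifacts
    are recorded in the returned :class:`SyntheticGroundTruth`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.n_channels
    t_samples = int(round(spec.duration_s * spec.fs))
    s_epoch = int(round(spec.epoch_len_s * spec.fs))
    labels = _default_labels(m)

    # shared 1/f sources through a common mixing matrix; every channel
    # loads 1.0 on source 0 so pairwise correlation stays high
    k = max(1, spec.n_sources)
    sources = np.stack([pink_noise(t_samples, spec.background_exponent, rng)
                        for _ in range(k)])
    mixing = np.concatenate(
        [np.ones((m, 1)), rng.uniform(-0.3, 0.3, size=(m, k - 1))], axis=1)
    bg = mixing @ sources
    bg /= bg.std(axis=1, keepdims=True)
    data = bg * spec.background_amplitude_uv
    data += (spec.noise_floor_frac * spec.background_amplitude_uv
             * rng.standard_normal((m, t_samples)))

    true_paf = None
    if spec.alpha.amplitude_uv > 0:
        tgrid = np.arange(t_samples) / spec.fs
        phase = rng.uniform(0, 2 * np.pi)
        env = _slow_envelope(t_samples, spec.fs, spec.alpha.bandwidth_hz, rng)
        carrier = np.sin(2 * np.pi * spec.alpha.peak_hz * tgrid + phase)
        data += (_alpha_weights(labels, spec.alpha)[:, None]
                 * spec.alpha.amplitude_uv * env * carrier)
        true_paf = spec.alpha.peak_hz

    if spec.line_noise.amplitude_uv > 0:
        tgrid = np.arange(t_samples) / spec.fs
        line = spec.line_noise.amplitude_uv * np.sin(
            2 * np.pi * spec.line_noise.freq_hz * tgrid + rng.uniform(0, 2 * np.pi))
        chans = spec.line_noise.channels or tuple(range(m))
        for c in chans:
            data[c] += line

    bad_channels: dict[int, str] = {}
    bad_epochs: dict[int, str] = {}
    n_epochs = t_samples // s_epoch
    for art in spec.artifacts:
        ch = art.channel
        if ch is None and art.kind != "blink":
            ch = int(rng.integers(0, m))
        if art.kind == "flat_channel":
            data[ch] = 0.0
            bad_channels[ch] = art.kind
        elif art.kind == "noisy_channel":
            mag = 5.0 if art.magnitude is None else art.magnitude
            data[ch] += (mag * spec.background_amplitude_uv
                         * rng.standard_normal(t_samples))
            bad_channels[ch] = art.kind
        elif art.kind == "uncorrelated_channel":
            sd = data[ch].std()
            data[ch] = pink_noise(t_samples, spec.background_exponent, rng) * sd
            bad_channels[ch] = art.kind
        elif art.kind == "burst_epoch":
            mag = 20.0 if art.magnitude is None else art.magnitude
            epochs = art.epochs or (int(rng.integers(0, n_epochs)),)
            for e in epochs:
                lo = e * s_epoch
                data[ch, lo:lo + s_epoch] += (
                    mag * data[ch].std() * _burst_shape(s_epoch, spec.fs, rng))
                bad_epochs[e] = art.kind
        elif art.kind == "blink":
            mag = 200.0 if art.magnitude is None else art.magnitude
            frontal = [i for i, lb in enumerate(labels) if lb in _FRONTAL] or [0]
            epochs = art.epochs or (int(rng.integers(0, n_epochs)),)
            for e in epochs:
                lo = e * s_epoch
                shape = _blink_shape(s_epoch, spec.fs, rng)
                for i in frontal:
                    w = 1.0 if labels[i].startswith("Fp") else 0.5
                    data[i, lo:lo + s_epoch] += mag * w * shape
                bad_epochs[e] = art.kind

    if session is None:
        session = SessionMeta(date=_dt.date(2024, 1, 1),
                              participant_id=f"synthetic-{spec.seed}")
    rec = Recording(data=data, fs=spec.fs, labels=labels,
                    condition=condition, session=session)
    return rec, SyntheticGroundTruth(bad_channels=bad_channels,
                                     bad_epochs=bad_epochs, true_paf=true_paf)


# ---------------------------------------------------------------------------
# Cohorts

DEFAULT_TEAMS = ("NCR1", "NCR2", "TN1")
DEFAULT_AGE_GROUPS = ("15-24", "25-44", "45-64", "65-74")


def generate_cohort(n_recordings: int, seed: int,
                    base_spec: SyntheticSpec | None = None,
                    alpha_range: tuple[float, float] = (8.0, 11.0),
                    artifact_rate: float = 0.0,
                    teams: tuple[str, ...] = DEFAULT_TEAMS,
                    devices_per_team: int = 2,
                    conditions: tuple[str, ...] = ("EC",),
                    start_date: _dt.date = _dt.date(2024, 1, 8),
                    n_days: int = 5,
                    age_groups: tuple[str, ...] | None = None,
                    paf_by_age: dict[str, float] | None = None,
                    ) -> list[tuple[Recording, SyntheticGroundTruth]]:
    """Generate a cohort with session metadata for dashboards and
    contrasts.

    Alpha peaks are drawn uniformly on the 0.5 Hz analysis grid inside
    ``alpha_range`` unless ``paf_by_age`` pins each age group to a
    peak (emulating the decline of peak alpha frequency with adult
    age).  With probability ``artifact_rate`` a recording receives one
    random channel artifact.  All randomness derives from ``seed``.
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    lo, hi = alpha_range
    if hi < lo:
        raise ValueError("alpha_range must be (lo, hi) with lo <= hi")
    base = base_spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    grid = np.arange(np.ceil(lo * 2) / 2, hi + 1e-9, 0.5)
    if grid.size == 0:
        raise ValueError("alpha_range contains no 0.5 Hz grid point")
    if age_groups is None:
        age_groups = (tuple(paf_by_age) if paf_by_age else DEFAULT_AGE_GROUPS)
    out = []
    for i in range(n_recordings):
        team = teams[i % len(teams)]
        device = f"{team}-dev{int(rng.integers(devices_per_team))}"
        cond = conditions[i % len(conditions)]
        date = start_date + _dt.timedelta(days=int(rng.integers(n_days)))
        age = age_groups[int(rng.integers(len(age_groups)))]
        sex = ("male", "female")[int(rng.integers(2))]
        indoor = ("indoor", "outdoor")[int(rng.integers(2))]
        if paf_by_age is not None:
            peak = paf_by_age[age]
        else:
            peak = float(grid[rng.integers(grid.size)])
        artifacts: tuple[ArtifactSpec, ...] = ()
        if artifact_rate > 0 and rng.random() < artifact_rate:
            kind = ("flat_channel", "noisy_channel",
                    "uncorrelated_channel")[int(rng.integers(3))]
            artifacts = (ArtifactSpec(
                kind=kind, channel=int(rng.integers(base.n_channels))),)
        spec = replace(
            base, seed=int(rng.integers(2 ** 31)),
            alpha=replace(base.alpha, peak_hz=peak), artifacts=artifacts)
        session = SessionMeta(date=date, team_id=team, device_id=device,
                              participant_id=f"P{i:04d}", sex=sex,
                              indoor_outdoor=indoor, age_group=age)
        out.append(generate_recording(spec, condition=cond, session=session))
    return out
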