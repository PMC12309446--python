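"""Recording containers, montage validation and EDF/CSV input-output.

A :class:`Recording` is a channels-by-samples matrix in microvolts with
its sampling rate, ordered channel labels, recording condition (eyes
closed, eyes open or task) and session metadata.  Two interchange
formats are supported: a plain CSV matrix (header row of labels, one
row per sample, values in microvolts — loss-free, used for tests and
pipelines) and 16-bit EDF.  Session metadata travels as a JSON sidecar
``<basename>.session.json``.

EDF reading goes through :mod:`mne`.  EDF writing is implemented here
(standard 256-byte header, 16-bit little-endian samples): note that the
EDF sample encoding quantizes each channel to 16 bits over its physical
range, so an EDF round trip is accurate only to ~range/2**15.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import os
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

CONDITIONS = ("EC", "EO", "TASK")
N_EXPECTED_CHANNELS = 16


class FormatError(ValueError):
    """Unreadable or structurally invalid recording file."""


class MontageError(ValueError):
    """Channel label outside the standard and alternate sets."""


@dataclass(frozen=True)
class SessionMeta:
    """Session-level grouping keys for dashboards and contrasts."""

    date: _dt.date
    team_id: str = "unknown-team"
    device_id: str = "unknown-device"
    participant_id: str = "anonymous"
    indoor_outdoor: str = "unknown"
    sex: str = "unknown"
    age_group: str = "unknown"

    def __post_init__(self) -> None:
        if not isinstance(self.date, _dt.date):
            raise ValueError(f"date must be a datetime.date, got {self.date!r}")
        for name in ("team_id", "device_id", "participant_id"):
            if not getattr(self, name):
                raise ValueError(f"SessionMeta.{name} must be a non-empty string")
        if self.indoor_outdoor not in ("indoor", "outdoor", "unknown"):
            raise ValueError(f"invalid indoor_outdoor: {self.indoor_outdoor!r}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex: {self.sex!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "team_id", "device_id", "participant_id",
            "indoor_outdoor", "sex", "age_group")}
        d["date"] = self.date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMeta":
        d = dict(d)
        d["date"] = _dt.date.fromisoformat(d["date"])
        return cls(**d)


@dataclass
class Recording:
    """Multichannel EEG segment in microvolts.

    ``data`` has shape (M channels, T samples); ``labels`` has exactly
    M unique entries in recording order.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    condition: str = "EC"
    session: SessionMeta = field(
        default_factory=lambda: SessionMeta(date=_dt.date(1970, 1, 1)))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        m, t = self.data.shape
        if m < 1 or t < 1:
            raise ValueError("Recording.data must have >=1 channel and >=1 sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = list(self.labels)
        if len(self.labels) != m:
            raise ValueError(
                f"{len(self.labels)} labels for {m} channels")
        if len(set(self.labels)) != m:
            raise ValueError("channel labels must be unique")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def copy_with(self, **kw) -> "Recording":
        if "data" not in kw:
            kw["data"] = self.data.copy()
        return replace(self, **kw)


@dataclass(frozen=True)
class MontageReport:
    """Partition of the 16 expected electrodes into standard placements,
    accepted alternates and missing sites."""

    n_standard: int
    n_nonstandard: int
    n_missing: int

    def __post_init__(self) -> None:
        total = self.n_standard + self.n_nonstandard + self.n_missing
        if total != N_EXPECTED_CHANNELS:
            raise ValueError(
                f"montage counts must partition {N_EXPECTED_CHANNELS}, got {total}")


# ---------------------------------------------------------------------------
# Montage

def load_montage(path: str | None = None) -> dict:
    """Load the montage definition (standard labels + alternates map).

    The shipped default documents the assumed 16-channel 10-20 subset;
    pass your own YAML to override it.
    """
    if path is None:
        src = resources.files("eegqc.data").joinpath("montage.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    standard = list(raw["standard"])
    alternates = {k: list(v) for k, v in raw["alternates"].items()}
    return {"standard": standard, "alternates": alternates}


def classify_montage(labels: Sequence[str],
                     montage: dict | str | None = None) -> MontageReport:
    """Count standard, alternate and missing electrodes among ``labels``.

    Each alternate label substitutes for one specific standard site;
    unknown labels raise :class:`MontageError` listing them.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    if montage is None or isinstance(montage, str):
        montage = load_montage(montage)
    standard = set(montage["standard"])
    alt_to_std = {alt: std for std, alts in montage["alternates"].items()
                  for alt in alts}
    unknown = [lb for lb in labels if lb not in standard and lb not in alt_to_std]
    if unknown:
        raise MontageError(f"unrecognized channel labels: {unknown}")
    covered: set[str] = set()
    n_standard = n_nonstandard = 0
    for lb in labels:
        site = lb if lb in standard else alt_to_std[lb]
        if site in covered:
            raise MontageError(f"site {site} covered by more than one electrode")
        covered.add(site)
        if lb in standard:
            n_standard += 1
        else:
            n_nonstandard += 1
    n_missing = N_EXPECTED_CHANNELS - n_standard - n_nonstandard
    return MontageReport(n_standard, n_nonstandard, n_missing)


# ---------------------------------------------------------------------------
# CSV

def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".session.json"


def _write_sidecar(path: str, rec: Recording) -> None:
    meta = {"fs": rec.fs, "condition": rec.condition,
            "session": rec.session.to_dict()}
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_sidecar(path: str) -> dict | None:
    sc = _sidecar_path(path)
    if not os.path.exists(sc):
        return None
    with open(sc) as fh:
        return json.load(fh)


def _read_csv(path: str, fs: float | None) -> tuple[np.ndarray, list[str], float | None]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise FormatError(f"{path}: empty file")
        labels = [h.strip() for h in header.split(",")]
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"{path}: no sample rows")
    if data.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} header columns but rows of width {data.shape[1]}")
    return data.T, labels, fs


# ---------------------------------------------------------------------------
# EDF (16-bit, single data-record fallback when fs is non-integer)

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _edf_num(value: float, width: int) -> tuple[bytes, float]:
    """Format a physical bound into an EDF header field; return the
    exact value the field parses back to, used for scaling."""
    for fmt in (f"%.{p}g" % value for p in range(6, 0, -1)):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii"), float(fmt)
    raise ValueError(f"cannot format {value} in {width} chars")


def _write_edf(path: str, rec: Recording) -> None:
    m, t = rec.data.shape
    if abs(rec.fs - round(rec.fs)) < 1e-9 and t % int(round(rec.fs)) == 0:
        spr, record_dur = int(round(rec.fs)), 1.0
        nrec = t // spr
    else:  # single record holding the whole recording
        spr, record_dur, nrec = t, t / rec.fs, 1
    pmins, pmaxs, digital = [], [], np.empty((m, t), dtype="<i2")
    for i in range(m):
        x = rec.data[i]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        lo_b, lo_v = _edf_num(lo, 8)
        hi_b, hi_v = _edf_num(hi, 8)
        if hi_v <= lo_v:
            hi_v = lo_v + 1.0
            hi_b, hi_v = _edf_num(hi_v, 8)
        pmins.append((lo_b, lo_v))
        pmaxs.append((hi_b, hi_v))
        scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (hi_v - lo_v)
        digital[i] = np.clip(
            np.round((x - lo_v) * scale) + _EDF_DIG_MIN,
            _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    d = rec.session.date
    hdr = b"".join([
        _edf_field("0", 8),
        _edf_field(rec.session.participant_id[:80], 80),
        _edf_field(f"Startdate {d.strftime('%d-%b-%Y').upper()}"[:80], 80),
        _edf_field(d.strftime("%d.%m.%y"), 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (m + 1), 8),
        _edf_field("", 44),
        _edf_field(nrec, 8),
        _edf_field(("%g" % record_dur)[:8], 8),
        _edf_field(m, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(lb[:16], 16) for lb in rec.labels),
        b"".join(_edf_field("", 80) for _ in range(m)),
        b"".join(_edf_field("uV", 8) for _ in range(m)),
        b"".join(p[0] for p in pmins),
        b"".join(p[0] for p in pmaxs),
        b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in range(m)),
        b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(m)),
        b"".join(_edf_field("", 80) for _ in range(m)),
        b"".join(_edf_field(spr, 8) for _ in range(m)),
        b"".join(_edf_field("", 32) for _ in range(m)),
    ])
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(nrec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(np.ascontiguousarray(block).tobytes())


def _read_edf(path: str) -> tuple[np.ndarray, list[str], float]:
    import mne
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne loads in volts; convert to microvolts
    return data, list(raw.ch_names), float(raw.info["sfreq"])


# ---------------------------------------------------------------------------
# Public read/write

def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".edf":
        return "edf"
    if ext in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer format of {path}; pass format explicitly")


def read_recording(path: str, format: str = "auto", condition: str | None = None,
                   session: SessionMeta | None = None,
                   fs: float | None = None) -> Recording:
    """Read a recording from EDF or CSV into microvolts.

    For CSV the sampling rate comes from ``fs`` or the session sidecar.
    ``condition`` and ``session`` override anything found in the
    sidecar.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        format = _infer_format(path)
    if format == "csv":
        sidecar = _read_sidecar(path)
        if fs is None and sidecar is not None:
            fs = sidecar.get("fs")
        if fs is None:
            raise ValueError("fs must be supplied (argument or sidecar) for CSV")
        if fs <= 0:
            raise ValueError("fs must be positive")
        data, labels, _ = _read_csv(path, fs)
    elif format == "edf":
        sidecar = _read_sidecar(path)
        data, labels, fs = _read_edf(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if condition is None:
        condition = (sidecar or {}).get("condition", "EC")
    if session is None and sidecar is not None and "session" in sidecar:
        session = SessionMeta.from_dict(sidecar["session"])
    kw = {} if session is None else {"session": session}
    return Recording(data=data, fs=float(fs), labels=labels,
                     condition=condition, **kw)


def write_recording(rec: Recording, path: str, format: str = "auto",
                    sidecar: bool = True) -> None:
    """Write a recording as CSV (loss-free) or 16-bit EDF, plus the
    session JSON sidecar."""
    if format == "auto":
        format = _infer_format(path)
    if format == "csv":
        header = ",".join(rec.labels)
        np.savetxt(path, rec.data.T, delimiter=",", header=header,
                   comments="", fmt="%.10g")
    elif format == "edf":
        _write_edf(path, rec)
    else:
        raise ValueError(f"unknown format {format!r}")
    if sidecar:
        _write_sidecar(path, rec)
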