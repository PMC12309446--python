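"""Daily field-team quality dashboard.

Each morning the field program gets a table with, for the report date
and year-to-date (same calendar year up to and including the date):
number of recordings, nonstandard and missing electrode counts, and
the percentage of bad channels and bad epochs — overall, per recording
condition, per research team and per device.

Percentages in the table cells are pooled (bad-count over total-count
across the scope, i.e. channel-count weighted); the unweighted mean of
per-recording percentages is emitted alongside since either convention
is used in practice.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, fields as _dc_fields

import pandas as pd

from eegqc.aggregate_stats import QCSummary

_SCOPES = ("overall", "task", "team", "device")


@dataclass
class DashboardRow:
    scope: str                      # overall | task | team | device
    scope_id: str
    n_recordings_on_date: int
    n_recordings_ytd: int
    n_nonstandard_on_date: int
    n_nonstandard_ytd: int
    n_missing_on_date: int
    n_missing_ytd: int
    pct_bad_channels_on_date: float
    pct_bad_channels_ytd: float
    pct_bad_epochs_on_date: float
    pct_bad_epochs_ytd: float
    mean_pct_bad_channels_on_date: float = 0.0
    mean_pct_bad_epochs_on_date: float = 0.0

    def __post_init__(self) -> None:
        if self.scope not in _SCOPES:
            raise ValueError(f"scope must be one of {_SCOPES}")
        if self.n_recordings_ytd < self.n_recordings_on_date:
            raise ValueError("YTD recording count below on-date count")


def _pooled(summaries: list[QCSummary]) -> dict:
    n_ch = sum(s.n_channels for s in summaries)
    n_ep = sum(s.n_epochs for s in summaries)
    bad_ch = sum(s.n_bad_channels for s in summaries)
    bad_ep = sum(s.n_bad_epochs for s in summaries)
    return {
        "n": len(summaries),
        "nonstd": sum(s.n_nonstandard for s in summaries),
        "missing": sum(s.n_missing for s in summaries),
        "pct_ch": 100.0 * bad_ch / n_ch if n_ch else 0.0,
        "pct_ep": 100.0 * bad_ep / n_ep if n_ep else 0.0,
        "mean_pct_ch": (sum(s.pct_bad_channels for s in summaries) / len(summaries)
                        if summaries else 0.0),
        "mean_pct_ep": (sum(s.pct_bad_epochs for s in summaries) / len(summaries)
                        if summaries else 0.0),
    }


def _row(scope: str, scope_id: str, on_date: list[QCSummary],
         ytd: list[QCSummary]) -> DashboardRow:
    d, y = _pooled(on_date), _pooled(ytd)
    return DashboardRow(
        scope=scope, scope_id=scope_id,
        n_recordings_on_date=d["n"], n_recordings_ytd=y["n"],
        n_nonstandard_on_date=d["nonstd"], n_nonstandard_ytd=y["nonstd"],
        n_missing_on_date=d["missing"], n_missing_ytd=y["missing"],
        pct_bad_channels_on_date=d["pct_ch"], pct_bad_channels_ytd=y["pct_ch"],
        pct_bad_epochs_on_date=d["pct_ep"], pct_bad_epochs_ytd=y["pct_ep"],
        mean_pct_bad_channels_on_date=d["mean_pct_ch"],
        mean_pct_bad_epochs_on_date=d["mean_pct_ep"])


def build_daily_report(summaries: list[QCSummary], report_date: _dt.date,
                       method: str = "FASTER") -> list[DashboardRow]:
    """Aggregate per-recording summaries into the daily report.

    Rows: one overall, one per condition (EC/EO/TASK), one per team,
    one per device — on-date and year-to-date side by side.  All
    summaries must carry session metadata with dates not after the
    report date.
    """
    method = method.upper()
    pool = [s for s in summaries if s.method == method]
    for s in pool:
        if s.session is None:
            raise ValueError(f"summary {s.recording_id} lacks session metadata")
        if s.session.date > report_date:
            raise ValueError(
                f"summary {s.recording_id} dated {s.session.date} is after "
                f"the report date {report_date}")
    ytd = [s for s in pool if s.session.date.year == report_date.year]
    on_date = [s for s in ytd if s.session.date == report_date]

    rows = [_row("overall", "all", on_date, ytd)]
    for cond in ("EC", "EO", "TASK"):
        rows.append(_row(
            "task", cond,
            [s for s in on_date if s.condition == cond],
            [s for s in ytd if s.condition == cond]))
    for scope, attr in (("team", "team_id"), ("device", "device_id")):
        levels = sorted({getattr(s.session, attr) for s in ytd})
        for lv in levels:
            rows.append(_row(
                scope, lv,
                [s for s in on_date if getattr(s.session, attr) == lv],
                [s for s in ytd if getattr(s.session, attr) == lv]))
    return rows


_COLUMNS = [f.name for f in _dc_fields(DashboardRow)]


def rows_to_frame(rows: list[DashboardRow]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in rows],
                        columns=_COLUMNS)


def render_report(rows: list[DashboardRow], format: str = "csv") -> str:
    """Serialize dashboard rows as CSV or a markdown table with a
    deterministic column order."""
    df = rows_to_frame(rows)
    if format == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False, float_format="%.6g")
        return buf.getvalue()
    if format == "markdown":
        show = df.copy()
        for c in show.columns:
            if c.startswith(("pct_", "mean_pct_")):
                show[c] = show[c].map(lambda v: f"{v:.1f}%")
        header = "| " + " | ".join(show.columns) + " |"
        sep = "|" + "|".join(["---"] * len(show.columns)) + "|"
        lines = ["| " + " | ".join(str(v) for v in row) + " |"
                 for row in show.itertuples(index=False)]
        return "\n".join([header, sep, *lines]) + "\n"
    raise ValueError(f"unknown format {format!r}")


def parse_report(text: str) -> list[DashboardRow]:
    """Inverse of render_report(format='csv')."""
    df = pd.read_csv(io.StringIO(text))
    rows = []
    for rec in df.to_dict("records"):
        for c in _COLUMNS:
            if c.startswith("n_"):
                rec[c] = int(rec[c])
        rows.append(DashboardRow(**{c: rec[c] for c in _COLUMNS}))
    return rows
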