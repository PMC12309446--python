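"""Build the daily field-team quality dashboard from a cohort.

Simulates a small multi-team cohort collected over a week, summarizes
every recording with FASTER, and renders the daily report: recordings,
nonstandard/missing electrodes and bad-channel/epoch percentages, on
the report date and year-to-date, overall / per condition / per team /
per device.
"""

import datetime as dt

from eegqc import build_daily_report, render_report, summarize_recording
from eegqc.simulate import SyntheticSpec, generate_cohort

pairs = generate_cohort(
    n_recordings=12,
    seed=4,
    base_spec=SyntheticSpec(duration_s=30.0),
    teams=("NCR1", "NCR2", "TN1"),
    conditions=("EC", "EO", "TASK"),
    artifact_rate=0.25,                       # a quarter of recordings get one bad channel
    start_date=dt.date(2024, 2, 12),
    n_days=4,
)

summaries = [summarize_recording(rec, "FASTER", recording_id=f"r{i:02d}")
             for i, (rec, _) in enumerate(pairs)]

report_date = max(s.session.date for s in summaries)
rows = build_daily_report(summaries, report_date, method="FASTER")
print(f"report date: {report_date}\n")
print(render_report(rows, format="markdown"))

# Team rows partition the overall counts; percentages are pooled
# (bad-count over total-count across the scope), with the unweighted
# per-recording mean in the trailing columns.
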