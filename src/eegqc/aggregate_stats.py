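"""Per-recording quality summaries and group-level statistics.

A recording reduces to the percentage of bad channels and bad epochs
per method; cohorts reduce to mean +/- SEM per group, standard t
tests between conditions, empirical CDFs, and a bootstrap comparison
for unequal group sizes: the larger group is repeatedly subsampled
(without replacement) to the size of the smaller, a two-sample t test
is run per draw, and the reported significance is the average p value
over the iterations (50 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from eegqc.config import QCConfig
from eegqc.faster_qc import ChannelQCResult, EpochQCResult, faster_bad_channels, faster_bad_epochs
from eegqc.prep_qc import prep_bad_channels, prep_bad_epochs
from eegqc.preprocessing import epoch, highpass
from eegqc.recording_io import Recording, SessionMeta, classify_montage


@dataclass
class QCSummary:
    """Quality of one recording under one method."""

    recording_id: str
    condition: str
    method: str
    pct_bad_channels: float
    pct_bad_epochs: float
    n_channels: int
    n_epochs: int
    n_bad_channels: int
    n_bad_epochs: int
    session: SessionMeta | None = None
    n_nonstandard: int = 0
    n_missing: int = 0

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "recording_id", "condition", "method", "pct_bad_channels",
            "pct_bad_epochs", "n_channels", "n_epochs", "n_bad_channels",
            "n_bad_epochs", "n_nonstandard", "n_missing")}
        if self.session is not None:
            d.update({f"session_{k}": v for k, v in self.session.to_dict().items()})
        return d


@dataclass
class GroupComparison:
    """Two-group contrast: means +/- SEM and a (possibly averaged)
    two-sided t-test p value."""

    group_a: str
    group_b: str
    group_a_mean: float
    group_a_sem: float
    group_b_mean: float
    group_b_sem: float
    p_value: float
    n_a: int
    n_b: int
    n_iterations: int = 1
    test: str = "t_test"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p value outside [0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def percent_bad(result: ChannelQCResult | EpochQCResult) -> float:
    """100 x flagged / total: one bad channel of 16 is 6.25%, one of
    64 is 1.5625% (printed 1.6% at one decimal)."""
    n = result.n_items
    if n == 0:
        raise ValueError("empty QC result")
    return 100.0 * float(result.bad.sum()) / n


def group_summary(values: np.ndarray) -> tuple[float, float, float]:
    """Sample mean, SD (ddof=1) and SEM = SD/sqrt(n)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("group_summary needs n >= 2")
    sd = float(np.std(v, ddof=1))
    return float(v.mean()), sd, sd / np.sqrt(v.size)


def bootstrap_compare(field_values: np.ndarray, benchmark: np.ndarray,
                      iters: int = 50, seed: int | None = None,
                      group_a: str = "field",
                      group_b: str = "benchmark") -> GroupComparison:
    """Average-p bootstrap comparison of a large field sample against a
    smaller benchmark.

    Each iteration subsamples len(benchmark) values from the field
    group without replacement and runs a two-sided Welch t test
    against the benchmark; the reported p value is the mean over
    iterations.  With iters=1 and equal sizes this degenerates to a
    single plain t test on the full samples.
    """
    f = np.asarray(field_values, dtype=float).ravel()
    b = np.asarray(benchmark, dtype=float).ravel()
    if b.size < 2:
        raise ValueError("benchmark group needs n >= 2")
    if f.size < b.size:
        raise ValueError(
            f"field group (n={f.size}) smaller than benchmark (n={b.size}); "
            "cannot subsample")
    rng = np.random.default_rng(seed)
    pvals = np.empty(iters)
    for i in range(iters):
        sub = f if f.size == b.size else rng.choice(f, size=b.size, replace=False)
        pvals[i] = sps.ttest_ind(sub, b, equal_var=False).pvalue
    fm, _, fsem = group_summary(f)
    bm, _, bsem = group_summary(b)
    return GroupComparison(
        group_a=group_a, group_b=group_b,
        group_a_mean=fm, group_a_sem=fsem,
        group_b_mean=bm, group_b_sem=bsem,
        p_value=float(pvals.mean()), n_a=f.size, n_b=b.size,
        n_iterations=iters, test="bootstrap_t", seed=seed)


def contrast_groups(summaries: list[QCSummary], key: str,
                    value: str = "pct_bad_channels") -> list[GroupComparison]:
    """Standard two-sided Welch t test between every unordered pair of
    levels of a session field (e.g. sex, indoor_outdoor, team_id).

    Levels with fewer than two recordings are skipped with a warning.
    """
    import warnings as _w

    groups: dict[str, list[float]] = {}
    for s in summaries:
        if key in ("condition", "method"):
            level = getattr(s, key)
        else:
            if s.session is None:
                continue
            level = getattr(s.session, key)
        groups.setdefault(str(level), []).append(getattr(s, value))
    usable = {}
    for level, vals in sorted(groups.items()):
        if len(vals) < 2:
            _w.warn(f"level {level!r} has n={len(vals)} < 2; skipped",
                    stacklevel=2)
            continue
        usable[level] = np.asarray(vals)
    if len(usable) < 2:
        raise ValueError(f"need >= 2 usable levels of {key!r}")
    out = []
    for a, b in combinations(sorted(usable), 2):
        va, vb = usable[a], usable[b]
        am, _, asem = group_summary(va)
        bm, _, bsem = group_summary(vb)
        if np.allclose(va, va[0]) and np.allclose(vb, vb[0]) and am == bm:
            p = 1.0  # identical degenerate groups: no evidence of difference
        else:
            p = float(sps.ttest_ind(va, vb, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        out.append(GroupComparison(
            group_a=a, group_b=b, group_a_mean=am, group_a_sem=asem,
            group_b_mean=bm, group_b_sem=bsem, p_value=p,
            n_a=va.size, n_b=vb.size, n_iterations=1, test="t_test"))
    return out


def empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF: sorted unique values and cumulative
    fractions reaching exactly 1 at the maximum."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empirical_cdf of empty sample")
    xs, counts = np.unique(v, return_counts=True)
    return xs, np.cumsum(counts) / v.size


def summarize_recording(rec: Recording, method: str,
                        cfg: QCConfig | None = None,
                        recording_id: str | None = None,
                        pre_filtered: bool = False,
                        montage: dict | str | None = None) -> QCSummary:
    """Run the full pipeline (high-pass, epoch, bad-channel and
    bad-epoch detection) for one method and reduce to a QCSummary.

    Montage counting is attempted from the channel labels; labels
    outside the montage leave the nonstandard/missing counts at zero.
    """
    cfg = cfg or QCConfig()
    method = method.upper()
    filtered = rec if pre_filtered else highpass(rec, cfg.highpass_hz)
    ep = epoch(filtered, cfg.epoch_len_s)
    if method == "FASTER":
        ch = faster_bad_channels(filtered, cfg)
        epo = faster_bad_epochs(ep, cfg)
    elif method == "PREP":
        ch = prep_bad_channels(filtered, cfg)
        epo = prep_bad_epochs(ep, cfg)
    else:
        raise ValueError(f"unknown method {method!r}")
    try:
        mr = classify_montage(rec.labels, montage)
        n_nonstd, n_miss = mr.n_nonstandard, mr.n_missing
    except ValueError:
        n_nonstd = n_miss = 0
    return QCSummary(
        recording_id=recording_id or rec.session.participant_id,
        condition=rec.condition, method=method,
        pct_bad_channels=percent_bad(ch), pct_bad_epochs=percent_bad(epo),
        n_channels=ch.n_items, n_epochs=epo.n_items,
        n_bad_channels=int(ch.bad.sum()), n_bad_epochs=int(epo.bad.sum()),
        session=rec.session, n_nonstandard=n_nonstd, n_missing=n_miss)
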