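"""Clinical outcome scoring: ARAT totals and release-time comparison.

The Action Research Arm Test (ARAT) has 19 items scored 0-3 (total
0-57), administered here in three conditions: no device, orthosis under
myoelectric control, orthosis under BCI control.  Hand release times —
seconds from arriving over the target to dropping a held object — are
compared between control modes with a two-sample t test (pooled-variance
Student's test by default, Welch optionally).

The packaged fixtures carry the trial's item-score table and release
times; stored serial clinical scales (Fugl-Meyer, Motricity Index,
Stroke Impact Scale, Modified Ashworth) are echoed as reference data,
not recomputed — their item-level inputs are not available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import SessionLog

ARAT_N_ITEMS = 19
ARAT_MAX_ITEM = 3

_CONDITIONS = ("no_brace", "emg_myopro", "bci_myopro")


def _data_text(name: str) -> str:
    return resources.files("bciloop.data").joinpath(name).read_text()


def load_arat_table() -> pd.DataFrame:
    """The packaged 19-item ARAT score table (rows = items, columns =
    conditions ``no_brace``, ``emg_myopro``, ``bci_myopro``)."""
    import io

    return pd.read_csv(io.StringIO(_data_text("arat_items.csv")))


def load_release_times() -> pd.DataFrame:
    """The packaged release-time table (one row per trial: condition in
    {BCI, EMG}, seconds)."""
    import io

    return pd.read_csv(io.StringIO(_data_text("release_times.csv")))


def load_reference_scales() -> dict:
    """Stored serial clinical-scale totals (reference data only)."""
    return json.loads(_data_text("reference_scales.json"))


def arat_total(table: pd.DataFrame, condition: str) -> int:
    """Sum the 19 item scores for one condition (range 0-57).

    Raises
    ------
    ValueError
        If the table does not have exactly 19 items, or any score falls
        outside {0, 1, 2, 3} (the offending item is named).
    """
    if condition not in table.columns:
        raise KeyError(f"condition {condition!r} not in table")
    if len(table) != ARAT_N_ITEMS:
        raise ValueError(f"ARAT table must have {ARAT_N_ITEMS} items, got {len(table)}")
    scores = table[condition]
    for item, score in zip(table["item"], scores):
        if not float(score).is_integer() or not 0 <= int(score) <= ARAT_MAX_ITEM:
            raise ValueError(f"score {score!r} out of range 0-3 for item {item!r}")
    return int(scores.sum())


@dataclass
class ReleaseTimeSet:
    """Release times (seconds, positive) for one control condition."""

    condition: str
    times: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times <= 0):
            raise ValueError("release times must be positive")

    @property
    def n(self) -> int:
        return len(self.times)


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def pooled_t_test(
    a: ReleaseTimeSet, b: ReleaseTimeSet, equal_var: bool = True
) -> TTestResult:
    """Two-sample two-tailed t test on release times.

    The default is the pooled-variance (Student) test with
    df = n1 + n2 - 2; ``equal_var=False`` gives the Welch variant with
    Satterthwaite degrees of freedom.
    """
    x, y = a.times, b.times
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = len(x) + len(y) - 2.0
    else:
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def release_times_from_log(log: SessionLog, condition: str = "sim") -> ReleaseTimeSet:
    """Extract release times from a closed-loop session log.

    Pairs each ``over_bin`` event with the following ``released`` event;
    cycles that timed out (``release_timeout``) or were never completed
    are excluded and counted.

    Raises
    ------
    ValueError
        If a ``released`` event precedes any pending ``over_bin``
        ("event order").
    """
    times: list[float] = []
    excluded = 0
    pending: float | None = None
    for t, ev in log.events:
        if ev == "over_bin":
            if pending is not None:
                excluded += 1
            pending = t
        elif ev == "released":
            if pending is None:
                raise ValueError("event order: release before over-bin")
            times.append(t - pending)
            pending = None
        elif ev == "release_timeout":
            if pending is not None:
                excluded += 1
                pending = None
    if pending is not None:
        excluded += 1
    return ReleaseTimeSet(condition=condition, times=np.asarray(times), n_excluded=excluded)


def outcome_report(
    arat: pd.DataFrame | None = None,
    release_sets: list[ReleaseTimeSet] | None = None,
    equal_var: bool = True,
) -> dict:
    """Summary document: ARAT totals, release-time descriptives, t test,
    and the stored reference scales.

    Returns a JSON-serializable dict; :func:`report_markdown` renders it.
    """
    report: dict = {"reference_scales": load_reference_scales()}

    if arat is not None and len(arat):
        report["arat_totals"] = {
            cond: arat_total(arat, cond) for cond in _CONDITIONS if cond in arat.columns
        }
    else:
        report["arat_totals"] = "no data"

    if release_sets:
        desc = {}
        for rs in release_sets:
            desc[rs.condition] = {
                "n": rs.n,
                "mean_s": float(rs.times.mean()) if rs.n else float("nan"),
                "sd_s": float(rs.times.std(ddof=1)) if rs.n > 1 else float("nan"),
                "n_excluded": rs.n_excluded,
            }
        report["release_times"] = desc
        if len(release_sets) == 2 and all(rs.n >= 2 for rs in release_sets):
            t, df, p = pooled_t_test(release_sets[0], release_sets[1], equal_var=equal_var)
            report["t_test"] = {
                "variant": "pooled" if equal_var else "welch",
                "t": t,
                "df": df,
                "p_two_tailed": p,
            }
    else:
        report["release_times"] = "no data"
    return report


def report_markdown(report: dict) -> str:
    """Render an outcome report dict as Markdown."""
    lines = ["# Outcome report", ""]
    lines.append("## ARAT totals")
    if isinstance(report["arat_totals"], dict):
        for cond, total in report["arat_totals"].items():
            lines.append(f"- {cond}: {total} / 57")
    else:
        lines.append("_no data_")
    lines.append("")
    lines.append("## Release times")
    if isinstance(report["release_times"], dict):
        for cond, d in report["release_times"].items():
            lines.append(
                f"- {cond}: n={d['n']}, mean={d['mean_s']:.2f} s, "
                f"sd={d['sd_s']:.2f} s, excluded={d['n_excluded']}"
            )
        if "t_test" in report:
            tt = report["t_test"]
            lines.append(
                f"- {tt['variant']} two-sample t: t={tt['t']:.3f}, "
                f"df={tt['df']:.1f}, p={tt['p_two_tailed']:.3f}"
            )
    else:
        lines.append("_no data_")
    lines.append("")
    lines.append("## Stored reference scales (not recomputed)")
    ref = report["reference_scales"]
    for key, val in ref.items():
        if key == "note":
            continue
        lines.append(f"- {key}: {json.dumps(val)}")
    return "\n".join(lines) + "\n"
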