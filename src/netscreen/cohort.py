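"""Cohort-level summary statistics: Kaplan–Meier, log-rank, 2×2 tables.

Replays the clinical side of a two-arm observational cohort from
patient-level survival records and adverse-event count tables:
product-limit survival curves with their medians, the two-group log-rank
test, Pearson chi-square (with optional Yates continuity correction) on
2×2 event-by-arm tables, and printed-style incidence percentages.

Two small fixtures transcribed from published summary tables ship with
the package: a nine-patient stage-D survival table and a
treatment-related adverse-event (TRAE) count table; load them with
:func:`load_stage_d_fixture` and :func:`load_trae_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "Contingency2x2",
    "KMResult",
    "km_curve",
    "logrank",
    "chi2_2x2",
    "incidence",
    "load_stage_d_fixture",
    "load_trae_fixture",
    "read_survival_table",
]

SURVIVAL_COLUMNS = ["id", "time_days", "event", "arm"]


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table {path} lacks column(s) {missing}")
    if (df["time_days"] < 0).any():
        raise ValueError("negative survival times")
    return df


def load_stage_d_fixture() -> pd.DataFrame:
    """Nine stage-D patients (5 exposure, 4 nonexposure), all events."""
    with resources.as_file(resources.files("netscreen") / "data" / "table3_stage_d.tsv") as p:
        return read_survival_table(p)


def load_trae_fixture() -> pd.DataFrame:
    """Adverse-event counts per arm with the printed percentages."""
    with resources.as_file(resources.files("netscreen") / "data" / "table4_trae.tsv") as p:
        return pd.read_csv(p, sep="\t")


@dataclass(frozen=True)
class Contingency2x2:
    """event/no-event × exposure/nonexposure counts (a,b / c,d)."""

    a: int  # exposure, event
    b: int  # exposure, no event
    c: int  # nonexposure, event
    d: int  # nonexposure, no event

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class KMResult:
    """A product-limit curve: event-time grid, S(t), and the median.

    ``median`` is the smallest observed time with S(t) <= 0.5; when the
    curve never reaches 0.5 (heavy censoring) it is NaN and
    ``median_defined`` is False.
    """

    times: np.ndarray  # event/censor time grid, ascending
    survival: np.ndarray  # S(t) at each grid time
    median: float
    median_defined: bool
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(table: pd.DataFrame, arm: str | None = None) -> KMResult:
    """Kaplan–Meier estimate for one arm (or the whole table)."""
    sub = table if arm is None else table[table["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no subjects in arm {arm!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_days"], event_observed=sub["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    defined = math.isfinite(med)
    return KMResult(
        times=times,
        survival=surv,
        median=med if defined else float("nan"),
        median_defined=defined,
        n=len(sub),
    )


def logrank(table: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p."""
    arms = sorted(table["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"log-rank needs exactly 2 arms, got {arms}")
    a = table[table["arm"] == arms[0]]
    b = table[table["arm"] == arms[1]]
    res = _ll_logrank(
        a["time_days"], b["time_days"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def chi2_2x2(tbl: Contingency2x2, correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2×2, Yates continuity correction by default.

    Raises on a zero margin (a row or column of zeros), where the
    chi-square approximation collapses — use an exact test there.
    """
    arr = tbl.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table; use Fisher's exact test")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def incidence(tbl: Contingency2x2, arm: str) -> int:
    """Incidence percentage for one arm, rounded half-up to an integer."""
    if arm == "exposure":
        events, total = tbl.a, tbl.a + tbl.b
    elif arm == "nonexposure":
        events, total = tbl.c, tbl.c + tbl.d
    else:
        raise ValueError(f"unknown arm {arm!r}")
    if total == 0:
        raise ValueError(f"arm {arm!r} has no subjects")
    return int(math.floor(100 * events / total + 0.5))
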