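"""Kaplan-Meier estimation, log-rank testing and combined molecular risk.

The combined molecular-risk rule labels a patient high-risk if they
carry either a retained chromatin-remodeling gene mutation
(MLL3/KDM6A/GPS2/ZMYM3) or i17q — the disjunction of the two prognostic
markers. Survival analyses are run over the grid of endpoint (OS, DFS)
x clinical subset (standard-risk only, all patients) x stratifier
(mutation, i17q, combined).

The product-limit estimator and the two-group log-rank test are
implemented directly (events precede censorings at tied times, no
continuity correction, chi-square reference with 1 df); the test suite
cross-checks both against an independent survival library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_combined_risk",
    "km_curve",
    "logrank_test",
    "run_survival_analysis",
    "SurvivalCurve",
]

ENDPOINTS = {"OS": ("os_time", "os_event"), "DFS": ("dfs_time", "dfs_event")}
STRATIFIERS = ("mutation", "i17q", "combined")


@dataclass
class SurvivalCurve:
    """Stepwise product-limit estimate at the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def assign_combined_risk(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``molecular_risk`` = ``high`` iff mutation-positive OR i17q-positive."""
    for col in ("mutation_positive", "i17q_positive"):
        if col not in records.columns:
            raise ValueError(f"clinical records lack column {col!r}")
        missing = records.index[records[col].isna()]
        if len(missing):
            ids = records.loc[missing, "patient_id"].tolist()
            raise ValueError(f"patients with missing {col}: {ids[:5]}")
    out = records.copy()
    high = out["mutation_positive"].astype(bool) | out["i17q_positive"].astype(bool)
    out["molecular_risk"] = np.where(high, "high", "low")
    return out


def _endpoint_arrays(records: pd.DataFrame, endpoint: str):
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}")
    tcol, ecol = ENDPOINTS[endpoint]
    times = records[tcol].to_numpy(dtype=float)
    events = records[ecol].to_numpy(dtype=bool)
    if (times < 0).any():
        raise ValueError("negative survival times")
    return times, events


def km_curve(records: pd.DataFrame, endpoint: str = "OS") -> SurvivalCurve:
    """Product-limit survival estimate for one endpoint.

    At tied times events are processed before censorings, i.e. a
    subject censored at an event time is still in the risk set for that
    event.
    """
    times, events = _endpoint_arrays(records, endpoint)
    if len(times) == 0:
        raise ValueError("no records")
    event_times = np.unique(times[events])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        r = int((times >= t).sum())  # censored-at-t subjects still at risk
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return SurvivalCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
        n=len(times),
    )


def logrank_test(
    records: pd.DataFrame,
    grouping: str | pd.Series,
    endpoint: str = "OS",
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Observed-minus-expected events in group 1 with hypergeometric
    variance at each distinct event time; chi-square with 1 df, no
    continuity correction.
    """
    labels = records[grouping] if isinstance(grouping, str) else grouping
    levels = sorted(pd.unique(labels.dropna()), key=str)
    if len(levels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {levels}")
    times, events = _endpoint_arrays(records, endpoint)
    g1 = (labels == levels[1]).to_numpy()
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("a log-rank group is empty")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & events).sum())
        d1 = int(((times == t) & events & g1).sum())
        if n == 0:
            raise ValueError(f"empty risk set at event time {t}")
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def _stratifier_labels(records: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "mutation":
        flags = records["mutation_positive"].astype(bool)
    elif stratifier == "i17q":
        flags = records["i17q_positive"].astype(bool)
    elif stratifier == "combined":
        flags = records["mutation_positive"].astype(bool) | records[
            "i17q_positive"
        ].astype(bool)
    else:
        raise ValueError(f"stratifier must be one of {STRATIFIERS}")
    return pd.Series(np.where(flags, "positive", "negative"), index=records.index)


def run_survival_analysis(
    records: pd.DataFrame,
    stratifier: str = "combined",
    endpoint: str = "DFS",
    subset: str = "all",
) -> dict:
    """One cell of the survival grid: subset, stratify, estimate, test.

    ``subset`` is ``"SR"`` (standard-risk patients only) or ``"all"``.
    Returns group sizes and event counts, per-group Kaplan-Meier curves,
    and the log-rank chi-square and p-value.
    """
    if subset not in ("SR", "all"):
        raise ValueError("subset must be 'SR' or 'all'")
    data = records if subset == "all" else records[records["risk_group"] == "SR"]
    if len(data) == 0:
        raise ValueError(f"no patients left after subset={subset!r}")
    labels = _stratifier_labels(data, stratifier)
    chi2, p = logrank_test(data, labels, endpoint)
    curves = {}
    sizes = {}
    events = {}
    tcol, ecol = ENDPOINTS[endpoint]
    for level in ("negative", "positive"):
        grp = data[labels == level]
        sizes[level] = int(len(grp))
        events[level] = int(grp[ecol].sum())
        curves[level] = km_curve(grp, endpoint)
    return {
        "endpoint": endpoint,
        "subset": subset,
        "stratifier": stratifier,
        "n": int(len(data)),
        "group_sizes": sizes,
        "group_events": events,
        "logrank_chi2": chi2,
        "logrank_p": p,
        "curves": curves,
    }


def full_survival_grid(records: pd.DataFrame) -> pd.DataFrame:
    """All endpoint x subset x stratifier cells as a tidy frame."""
    rows = []
    for endpoint in ENDPOINTS:
        for subset in ("SR", "all"):
            for strat in STRATIFIERS:
                try:
                    res = run_survival_analysis(records, strat, endpoint, subset)
                except ValueError:
                    continue
                rows.append(
                    {
                        "endpoint": endpoint,
                        "subset": subset,
                        "stratifier": strat,
                        "n": res["n"],
                        "n_positive": res["group_sizes"]["positive"],
                        "n_negative": res["group_sizes"]["negative"],
                        "logrank_chi2": res["logrank_chi2"],
                        "logrank_p": res["logrank_p"],
                    }
                )
    return pd.DataFrame(rows)
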