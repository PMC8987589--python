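"""Cohort-level statistics: Pearson correlations, Kaplan–Meier curves,
log-rank tests, median splits and assay-concordance comparison.

Conventions: a Pearson R above 0.5 is reported as a strong correlation;
survival comparisons use the unweighted (Mantel–Haenszel) log-rank test
with p from the chi-square upper tail; no multiple-testing correction is
applied by default (Benjamini–Hochberg available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .paired_dynamics import DynamicsClass, GeneDynamics

STRONG_CORRELATION_R = 0.5


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    method: str


@dataclass
class SurvivalGrouping:
    """Per-patient group label plus survival time (months) and 0/1 event."""

    labels: list[str]
    times: list[float]
    events: list[int]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.times) == len(self.events)):
            raise ValueError("labels, times and events must align")
        groups = set(self.labels)
        if len(groups) < 2:
            raise ValueError("need two or more non-empty groups")
        if any(t < 0 for t in self.times):
            raise ValueError("negative survival time")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value (t transform, n-2 df).

    Pairs with a missing value in either vector are dropped listwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimate as a (time, survival) step table.

    Censored subjects (event 0) leave the risk set without producing a step.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank(grouping: SurvivalGrouping) -> TestResult:
    """Two-group unweighted log-rank test (chi-square with 1 df)."""
    groups = sorted(set(grouping.labels))
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    lab = np.asarray(grouping.labels)
    t = np.asarray(grouping.times, dtype=float)
    e = np.asarray(grouping.events, dtype=int)
    a, b = groups
    res = logrank_test(t[lab == a], t[lab == b], e[lab == a], e[lab == b])
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_per_group={a: int((lab == a).sum()), b: int((lab == b).sum())},
        method="logrank",
    )


def median_split(values) -> list[str]:
    """Label each value high/low by the median; ties (== median) go low.

    Missing values get an empty label and are excluded from the median.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if len(finite) < 2:
        raise ValueError("need at least 2 non-missing values")
    med = float(np.median(finite))
    return ["" if not np.isfinite(v) else ("low" if v <= med else "high")
            for v in arr]


def survival_by_gene(gds: list[GeneDynamics], patients, gene: str,
                     resistance_only: bool = False) -> SurvivalGrouping:
    """Altered/unaltered survival grouping for one gene.

    A patient is altered when their gene-level dynamics class for ``gene``
    is non-STABLE (or resistance-direction only, if requested).
    """
    altered = set()
    for g in gds:
        if g.gene != gene or g.cls is DynamicsClass.STABLE:
            continue
        if resistance_only and not g.cls.resistance_direction:
            continue
        altered.add(g.patient_id)
    labels, times, events = [], [], []
    for p in patients:
        labels.append("altered" if p.patient_id in altered else "unaltered")
        times.append(p.survival_time)
        events.append(p.event)
    return SurvivalGrouping(labels=labels, times=times, events=events)


def assay_concordance(vaf_a, vaf_b, positivity_threshold: float = 0.01,
                      ) -> dict:
    """Generic two-assay VAF comparison (e.g. exome vs digital PCR).

    Returns the Pearson correlation of paired VAFs plus a 2x2 concordance
    table at a positivity threshold, with the concordant fraction.
    """
    a = np.asarray(vaf_a, dtype=float)
    b = np.asarray(vaf_b, dtype=float)
    r, p = pearson(a, b)
    pos_a, pos_b = a >= positivity_threshold, b >= positivity_threshold
    table = {
        "both_positive": int((pos_a & pos_b).sum()),
        "a_only": int((pos_a & ~pos_b).sum()),
        "b_only": int((~pos_a & pos_b).sum()),
        "both_negative": int((~pos_a & ~pos_b).sum()),
    }
    concordant = table["both_positive"] + table["both_negative"]
    return {"r": r, "p": p, "table": table,
            "concordance": concordant / len(a)}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def write_stats_report(results: dict[str, TestResult], path) -> None:
    rows = [{"comparison": name,
             "n": ";".join(f"{k}={v}" for k, v in r.n_per_group.items()),
             "statistic": round(r.statistic, 6),
             "p_value": r.p_value, "method": r.method}
            for name, r in results.items()]
    pd.DataFrame(rows, columns=["comparison", "n", "statistic", "p_value",
                                "method"]).to_csv(path, sep="\t", index=False)
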