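"""Group statistics on sampled lifetime values.

Each sample is reduced to the mean of its randomly sampled pixels per
channel; groups (tissue class, tumor grade, or intraoperative fluorescence
status) are summarized by median and 25/75% quantiles of the per-sample
means, and compared pairwise with two-tailed Mann-Whitney U tests at
alpha = 5%.  No multiple-testing correction is applied (documented as a
limitation); the non-parametric test choice reflects the small group sizes.

A ``pooled`` mode computing the summaries over all sampled pixels rather
than per-sample means is available for sensitivity analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "SampleSummary",
    "GroupSummary",
    "TestResult",
    "summarize_samples",
    "summarize_groups",
    "mann_whitney_u",
    "pairwise_comparisons",
]

GROUP_KEYS = {"tissue", "grade", "ala"}
CHANNEL_COLS = {"NADH": "mean_tau_nadh_ns", "PPIX": "mean_tau_ppix_ns"}

# exact enumeration is cheap up to this pooled size; beyond it (or with ties)
# the normal approximation with tie and continuity correction is used
EXACT_MAX_POOLED = 12


@dataclass(frozen=True)
class SampleSummary:
    patient_id: int
    sample_id: str
    grade: str
    tissue: str
    ala: str
    mean_tau_nadh_ns: float
    mean_tau_ppix_ns: float


@dataclass(frozen=True)
class GroupSummary:
    key: str  # grouping key (tissue | grade | ala)
    label: str
    n_samples: int
    nadh_median_ns: float
    nadh_q25_ns: float
    nadh_q75_ns: float
    ppix_median_ns: float
    ppix_q25_ns: float
    ppix_q75_ns: float


@dataclass(frozen=True)
class TestResult:
    group_a: str
    group_b: str
    channel: str
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_a: int
    n_b: int
    significant: bool
    low_n: bool = False


def summarize_samples(cohort_table: pd.DataFrame) -> pd.DataFrame:
    """One row per sample: mean of its sampled NADH and PPIX lifetimes.

    Samples contributing zero rows simply do not appear (they were already
    reported unusable upstream).
    """
    grouped = cohort_table.groupby("sample_id", sort=True)
    out = grouped.agg(
        patient_id=("patient_id", "first"),
        grade=("grade", "first"),
        tissue=("tissue", "first"),
        ala=("ala", "first"),
        mean_tau_nadh_ns=("tau_nadh_ns", "mean"),
        mean_tau_ppix_ns=("tau_ppix_ns", "mean"),
        n_points=("tau_nadh_ns", "size"),
    ).reset_index()
    return out


def summarize_groups(
    summaries: pd.DataFrame, key: str, pooled_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Median and 25/75% quantiles of per-sample means within each label.

    Quantiles use linear interpolation between order statistics (type 7).
    If ``pooled_table`` is given, statistics are instead computed over all
    sampled pixel values (sensitivity mode).
    """
    if key not in GROUP_KEYS:
        raise ValueError(f"unknown grouping key {key!r}; choose from {GROUP_KEYS}")
    if pooled_table is not None:
        df = pooled_table
        cols = {"NADH": "tau_nadh_ns", "PPIX": "tau_ppix_ns"}
        n_col = "sample_id"
    else:
        df = summaries
        cols = CHANNEL_COLS
        n_col = "sample_id"
    rows = []
    for label, sub in df.groupby(key, sort=True):
        row: dict = {
            "key": key,
            "label": label,
            "n_samples": sub[n_col].nunique(),
        }
        for channel, col in cols.items():
            vals = sub[col].to_numpy(dtype=float)
            prefix = channel.lower()
            row[f"{prefix}_median_ns"] = float(np.median(vals))
            row[f"{prefix}_q25_ns"] = float(np.percentile(vals, 25))
            row[f"{prefix}_q75_ns"] = float(np.percentile(vals, 75))
        rows.append(row)
    return pd.DataFrame(rows)


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, *, channel: str = "", labels: tuple[str, str] = ("x", "y")
) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    U is computed from rank sums with midranks for ties.  The p-value uses
    exact enumeration of the permutation distribution when the pooled size is
    at most 12 and no ties are present, otherwise a normal approximation with
    tie correction and continuity correction.  The test is symmetric in its
    arguments, and two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size

    if np.all(pooled == pooled[0]):
        u = n1 * n2 / 2.0
        # p is exactly 1 by symmetry, no approximation involved
        return TestResult(labels[0], labels[1], channel, u, 1.0, "exact",
                          n1, n2, significant=False, low_n=(min(n1, n2) < 2))

    exact = (n1 + n2 <= EXACT_MAX_POOLED) and not _has_ties(pooled)
    method = "exact" if exact else "normal_approx"
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u = float(res.statistic)  # U for the first sample
    p = float(min(res.pvalue, 1.0))
    if u == n1 * n2 / 2.0:
        # dead-center U: the two-sided p is 1 by symmetry
        p = 1.0
    return TestResult(
        labels[0], labels[1], channel, u, p, method, n1, n2,
        significant=p < 0.05, low_n=(min(n1, n2) < 2),
    )


def pairwise_comparisons(
    summaries: pd.DataFrame, key: str, channel: str
) -> pd.DataFrame:
    """Mann-Whitney tests for all unordered group pairs on one channel.

    Per-sample means are compared; results carry an ``alpha = 0.05``
    significance flag and a ``low_n`` flag for single-sample groups.  No
    multiplicity correction is applied.
    """
    if key not in GROUP_KEYS:
        raise ValueError(f"unknown grouping key {key!r}")
    col = CHANNEL_COLS[channel]
    groups = {
        label: sub[col].to_numpy(dtype=float)
        for label, sub in summaries.groupby(key, sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    rows = []
    for (la, xa), (lb, xb) in itertools.combinations(groups.items(), 2):
        res = mann_whitney_u(xa, xb, channel=channel, labels=(str(la), str(lb)))
        rows.append(
            {
                "group_a": res.group_a,
                "group_b": res.group_b,
                "channel": channel,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
                "method": res.method,
                "significant": res.significant,
                "low_n": res.low_n,
            }
        )
    return pd.DataFrame(rows)
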