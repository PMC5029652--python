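"""Xenograft tumor-growth analysis: caliper volumes, relative tumor volume
(RTV) and nonparametric group comparison.

Tumor volume from two perpendicular caliper diameters uses the standard
V = (width² × length) / 2 with width = min(d1, d2) (an ellipsoid variant,
V = π/6·d1·d2·(d1+d2)/2, is available via ``formula="ellipsoid"``).  RTV is
the final volume divided by the baseline volume, where baseline is the last
measurement at or before the first dosing day; RTV ≤ 1 (boundary included)
classifies a mouse as responding — tumor stabilization or shrinkage.

Groups are compared with a two-sided Mann–Whitney rank-sum test: exact by
enumeration of the permutation distribution of the rank sum when the
combined sample size is ≤ 16 (the study's 8–9 mice per arm keep pairwise
comparisons on this path), otherwise the tie-corrected normal
approximation.  Significance tiers: * p<0.05, ** p<0.005, *** p<0.0005.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SchemaError

GROUPS = ("control", "drug_a", "drug_b", "combination")
TUMOR_COLUMNS = ["mouse", "group", "day"]  # plus d1_mm/d2_mm or volume_mm3

EXACT_MAX_N = 16  # combined-sample cutoff between exact and asymptotic paths
TIERS = ((0.0005, "***"), (0.005, "**"), (0.05, "*"))


def tumor_volume(d1, d2, formula: str = "standard"):
    """Volume (mm³) from two perpendicular diameters (mm)."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise DomainError("diameters must be > 0")
    width = np.minimum(d1, d2)
    length = np.maximum(d1, d2)
    if formula == "standard":
        v = width**2 * length / 2.0
    elif formula == "ellipsoid":
        v = np.pi / 6.0 * d1 * d2 * (d1 + d2) / 2.0
    else:
        raise ValueError(f"unknown volume formula {formula!r}")
    return float(v) if v.ndim == 0 else v


@dataclass
class MouseRecord:
    """One animal's volume series with derived baseline, RTV and response."""

    mouse: str
    group: str
    measurements: pd.DataFrame  # columns day, volume_mm3 (day ascending)
    treatment_start_day: float = 0.0

    def __post_init__(self) -> None:
        m = self.measurements
        days = m["day"].to_numpy(dtype=float)
        if not np.all(np.diff(days) > 0):
            raise DomainError(f"mouse {self.mouse}: days must be strictly increasing")
        if np.any(m["volume_mm3"].to_numpy() <= 0):
            raise DomainError(f"mouse {self.mouse}: volumes must be > 0")

    @property
    def baseline_day(self) -> float:
        m = self.measurements
        pre = m[m["day"] <= self.treatment_start_day]
        if pre.empty:
            raise DomainError(
                f"mouse {self.mouse}: no measurement at or before day "
                f"{self.treatment_start_day:g}"
            )
        return float(pre["day"].iloc[-1])

    @property
    def v0(self) -> float:
        m = self.measurements
        return float(m.loc[m["day"] == self.baseline_day, "volume_mm3"].iloc[0])

    @property
    def rtv(self) -> float:
        if self.measurements["day"].iloc[-1] <= self.treatment_start_day:
            raise DomainError(f"mouse {self.mouse}: no post-treatment measurement")
        return float(self.measurements["volume_mm3"].iloc[-1]) / self.v0

    @property
    def response(self) -> bool:
        """Tumor stabilization or shrinkage, defined as RTV ≤ 1."""
        return self.rtv <= 1.0


def relative_tumor_volume(record: MouseRecord, treatment_start_day: float | None = None) -> float:
    """Final / baseline volume for one mouse; baseline is the last
    measurement at or before the treatment start day."""
    if treatment_start_day is not None:
        record = MouseRecord(
            record.mouse, record.group, record.measurements, treatment_start_day
        )
    return record.rtv


def add_volumes(df: pd.DataFrame, formula: str = "standard") -> pd.DataFrame:
    """Return a copy with a ``volume_mm3`` column, computed from the caliper
    diameters when not already present."""
    missing = [c for c in TUMOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tumor table missing column(s): {', '.join(missing)}")
    if "volume_mm3" in df.columns:
        return df
    if not {"d1_mm", "d2_mm"}.issubset(df.columns):
        raise SchemaError("tumor table needs volume_mm3 or d1_mm + d2_mm")
    df = df.copy()
    df["volume_mm3"] = tumor_volume(
        df["d1_mm"].to_numpy(), df["d2_mm"].to_numpy(), formula
    )
    return df


def read_tumor_table(path: str | Path, formula: str = "standard") -> pd.DataFrame:
    """Read a tumor CSV (mouse, group, day + d1_mm/d2_mm or volume_mm3) and
    return it with a ``volume_mm3`` column computed where needed."""
    return add_volumes(pd.read_csv(path), formula)


def mouse_records(df: pd.DataFrame, treatment_start_day: float = 0.0) -> list[MouseRecord]:
    out = []
    for (mouse, group), m in df.groupby(["mouse", "group"], sort=True):
        m = m.sort_values("day")[["day", "volume_mm3"]].reset_index(drop=True)
        out.append(MouseRecord(str(mouse), str(group), m, treatment_start_day))
    return out


def rtv_table(df: pd.DataFrame, treatment_start_day: float = 0.0) -> pd.DataFrame:
    """Per-mouse RTV and response class from a long tumor table."""
    rows = [
        {
            "mouse": r.mouse, "group": r.group, "baseline_day": r.baseline_day,
            "v0_mm3": r.v0, "rtv": r.rtv, "response": r.response,
        }
        for r in mouse_records(df, treatment_start_day)
    ]
    return pd.DataFrame(rows)


def responder_fraction(rtv_values) -> float:
    """Fraction of animals with RTV ≤ 1 (boundary inclusive)."""
    v = np.asarray(rtv_values, dtype=float)
    if v.size == 0:
        raise DomainError("responder_fraction: empty group")
    return float(np.mean(v <= 1.0))


def _exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating the permutation distribution of the
    group-x rank sum (midranks, so ties are handled).

    p = P(|R − E[R]| ≥ |r_obs − E[R]|) under random assignment of the
    combined observations to the two groups.  Computed by dynamic
    programming over doubled midranks (always integers).
    """
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks2 = np.round(2.0 * stats.rankdata(combined)).astype(int)  # doubled midranks
    r_obs = int(ranks2[:n1].sum())
    total = ranks2.sum()
    n = n1 + n2
    # counts[k][s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in ranks2:
        for k in range(n1, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[n1]
    e_doubled = n1 * (n + 1)  # E[2R] = n1 * (N+1)
    dev = abs(r_obs - e_doubled)
    sums = np.arange(total + 1)
    p = dist[np.abs(sums - e_doubled) >= dev].sum() / comb(n, n1)
    return min(1.0, float(p))


@dataclass
class GroupComparison:
    """Two-sided Mann–Whitney comparison of two RTV (or any) value sets."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"
    stars: str

    @staticmethod
    def tier(p: float) -> str:
        for cutoff, stars in TIERS:
            if p < cutoff:
                return stars
        return "ns"


def compare_groups(
    rtv_a, rtv_b, label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Two-sided Mann–Whitney rank-sum test between two groups.

    Exact enumeration when combined n ≤ 16, else the tie-corrected normal
    approximation (with continuity correction).
    """
    x = np.asarray(rtv_a, dtype=float)
    y = np.asarray(rtv_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DomainError("each group needs n >= 2")
    n1, n2 = x.size, y.size
    r1 = stats.rankdata(np.concatenate([x, y]))[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if n1 + n2 <= EXACT_MAX_N:
        p = _exact_ranksum_pvalue(x, y)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "asymptotic"
    return GroupComparison(
        label_a, label_b, n1, n2, float(u1), p, method, GroupComparison.tier(p)
    )


def compare_all_groups(rtv: pd.DataFrame, reference: str | None = None) -> pd.DataFrame:
    """Pairwise comparisons of the RTV distributions of every group pair
    (or each group vs ``reference`` only)."""
    groups = sorted(rtv["group"].unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            if reference is not None and reference not in (ga, gb):
                continue
            cmpr = compare_groups(
                rtv.loc[rtv["group"] == ga, "rtv"],
                rtv.loc[rtv["group"] == gb, "rtv"],
                ga, gb,
            )
            rows.append(vars(cmpr))
    return pd.DataFrame(rows)


def growth_curve_summary(
    df: pd.DataFrame, treatment_start_day: float = 0.0
) -> pd.DataFrame:
    """Per group per day, mean ± SD of per-mouse relative volumes
    (volume / baseline).  Days a group was not measured are simply absent —
    never interpolated.  Groups of one animal get SD 0 and a flag."""
    records = mouse_records(df, treatment_start_day)
    rel = []
    for r in records:
        m = r.measurements
        rel.append(pd.DataFrame({
            "group": r.group, "mouse": r.mouse, "day": m["day"],
            "rel_volume": m["volume_mm3"] / r.v0,
        }))
    rel = pd.concat(rel, ignore_index=True)
    out = (
        rel.groupby(["group", "day"])["rel_volume"]
        .agg(mean_rel_volume="mean", sd_rel_volume=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    out["single_animal"] = out["n"] == 1
    out.loc[out["single_animal"], "sd_rel_volume"] = 0.0
    return out.sort_values(["group", "day"], kind="mergesort").reset_index(drop=True)
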