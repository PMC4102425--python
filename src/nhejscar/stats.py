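"""Cohort aggregation, significance tests, and FACS-based efficiency.

The study's statistical toolkit is deliberately simple and is reproduced as
such: percentages of junctions with a feature are compared by the pooled
two-proportion z statistic (the classic "two sample t-test between percents"
of desk calculators), per-junction sizes by the classical pooled-variance
unpaired t test, and end-joining efficiency is the ratio of GFP+ to DsRed+
cells, which normalizes repair events to transfection efficiency.  No
multiple-testing correction is applied by default (per-metric alpha), with a
Benjamini-Hochberg option available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .caller import CallParams


class DegenerateTestError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group or one-sample comparison."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    estimate1: float
    estimate2: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class FacsCounts:
    """Per-transfection flow-cytometry counts (typically 20,000 cells scored)."""

    sample: str
    n_gfp: int
    n_dsred: int
    n_total: int = 20_000

    def __post_init__(self) -> None:
        if min(self.n_gfp, self.n_dsred, self.n_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_gfp > self.n_total or self.n_dsred > self.n_total:
            raise ValueError("n_gfp and n_dsred cannot exceed n_total")


@dataclass(frozen=True)
class CohortSummary:
    """Per-cohort junction-spectrum metrics.

    Means are taken over junctions exhibiting the feature (deletion-bearing
    for ``mean_del``, insertion-bearing for ``mean_ins``) and reported as
    ``None`` when no junction exhibits it; ``include_zeros`` in
    :func:`summarize` switches to all-junction means.  Percentages are of all
    junctions in the cohort.
    """

    cohort: str
    n_junctions: int
    mean_del: Optional[float]
    pct_large_del: float
    mean_ins: Optional[float]
    pct_with_ins: float
    pct_mh: float
    pct_mmej: float

    def __post_init__(self) -> None:
        for pct in (self.pct_large_del, self.pct_with_ins, self.pct_mh, self.pct_mmej):
            if not (0.0 <= pct <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")
        if self.pct_mmej > self.pct_mh + 1e-9:
            raise ValueError("pct_mmej cannot exceed pct_mh")


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z test ("two sample t-test between percents").

    t = (p1 - p2) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)) with the pooled
    p_hat = (x1 + x2) / (n1 + n2); two-sided p from the normal reference
    distribution.  Antisymmetric in group order.  A pooled proportion of 0 or
    1 gives statistic 0, p = 1, flagged degenerate.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not (0 <= x <= n):
            raise ValueError(f"count {x} outside [0, {n}]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(0.0, 1.0, n1, n2, p1, p2, "two_proportion", degenerate=True)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(z, min(p, 1.0), n1, n2, p1, p2, "two_proportion")


def one_proportion_test(x: int, n: int, p0: float) -> TestResult:
    """One-sample z test of an observed proportion against a fixed p0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"count {x} outside [0, {n}]")
    p_obs = x / n
    if p0 <= 0.0 or p0 >= 1.0:
        return TestResult(0.0, 1.0, n, 0, p_obs, p0, "one_proportion", degenerate=True)
    z = (p_obs - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(z, min(p, 1.0), n, 0, p_obs, p0, "one_proportion")


def unpaired_t_test(sample1: Sequence[float], sample2: Sequence[float]) -> TestResult:
    """Classical pooled-variance two-sample t test (n1 + n2 - 2 df, two-sided)."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 values")
    m1, m2 = a.mean(), b.mean()
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if m1 == m2:
            return TestResult(0.0, 1.0, n1, n2, m1, m2, "unpaired_t")
        stat = math.inf if m1 > m2 else -math.inf
        return TestResult(stat, 0.0, n1, n2, m1, m2, "unpaired_t", degenerate=True)
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), n1 + n2 - 2)
    return TestResult(t, min(p, 1.0), n1, n2, m1, m2, "unpaired_t")


def _active(events: pd.DataFrame) -> pd.DataFrame:
    if "ad_retained" in events.columns and len(events):
        return events.loc[~events["ad_retained"].astype(bool)]
    return events


def summarize(
    events: pd.DataFrame,
    params: CallParams = CallParams(),
    cohort: str = "cohort",
    large_del_threshold: int = 500,
    mh_cap: Optional[int] = None,
    include_zeros: bool = False,
) -> CohortSummary:
    """Aggregate called events into the cohort's junction-spectrum metrics.

    Deletions are categorized into small (1..threshold) and large
    (> threshold); a deletion of exactly the threshold counts as small.
    ``mh_cap`` bounds the microhomology range counted (defaults to
    ``params.mmej_max``); events flagged ``ad_retained`` are excluded.
    """
    ev = _active(events)
    n = len(ev)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    cap = params.mmej_max if mh_cap is None else mh_cap
    dels = ev["del_total"].to_numpy()
    inss = ev["insertion_len"].to_numpy()
    mhs = ev["mh_len"].to_numpy()
    with_del = dels >= 1
    with_ins = inss >= 1
    if include_zeros:
        mean_del: Optional[float] = float(dels.mean())
        mean_ins: Optional[float] = float(inss.mean())
    else:
        mean_del = float(dels[with_del].mean()) if with_del.any() else None
        mean_ins = float(inss[with_ins].mean()) if with_ins.any() else None
    return CohortSummary(
        cohort=cohort,
        n_junctions=n,
        mean_del=mean_del,
        pct_large_del=100.0 * float((dels > large_del_threshold).mean()),
        mean_ins=mean_ins,
        pct_with_ins=100.0 * float(with_ins.mean()),
        pct_mh=100.0 * float(((mhs >= 1) & (mhs <= cap)).mean()),
        pct_mmej=100.0 * float(((mhs >= params.mmej_min) & (mhs <= cap)).mean()),
    )


def nhej_efficiency(counts: FacsCounts) -> float:
    """End-joining efficiency of one transfection: GFP+ / DsRed+ cells."""
    if counts.n_dsred == 0:
        raise ZeroDivisionError(
            f"sample {counts.sample!r}: no DsRed+ cells, efficiency undefined"
        )
    return counts.n_gfp / counts.n_dsred


def efficiency_summary(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and s.e.m. of replicate efficiency ratios (error-bar convention)."""
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one replicate")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def fold_change(young: Sequence[float], old: Sequence[float]) -> float:
    """Fold decline of efficiency with age: mean(young) / mean(old)."""
    y = np.asarray(young, dtype=float)
    o = np.asarray(old, dtype=float)
    if y.size == 0 or o.size == 0:
        raise ValueError("both cohorts must be non-empty")
    mo = o.mean()
    if mo == 0.0:
        raise ZeroDivisionError("old-cohort mean efficiency is 0; fold undefined")
    return float(y.mean() / mo)


_PROPORTION_METRICS = {
    "pct_large_del": lambda d, thr, p: (d["del_total"] > thr),
    "pct_with_ins": lambda d, thr, p: (d["insertion_len"] >= 1),
    "pct_mh": lambda d, thr, p: (d["mh_len"] >= 1) & (d["mh_len"] <= p.mmej_max),
    "pct_mmej": lambda d, thr, p: (d["mh_len"] >= p.mmej_min) & (d["mh_len"] <= p.mmej_max),
}


def compare_cohorts(
    young_events: pd.DataFrame,
    old_events: pd.DataFrame,
    params: CallParams = CallParams(),
    labels: tuple[str, str] = ("young", "old"),
    large_del_threshold: int = 500,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-metric young-vs-old comparison table.

    Proportion metrics use the pooled two-proportion z; size metrics
    (deletion/insertion means over feature-bearing junctions) use the
    unpaired t test on per-junction sizes.  ``bh_correct`` applies
    Benjamini-Hochberg across the table's p-values (off by default).
    """
    ya, oa = _active(young_events), _active(old_events)
    sy = summarize(ya, params, labels[0], large_del_threshold)
    so = summarize(oa, params, labels[1], large_del_threshold)
    rows = []
    for metric, mask_fn in _PROPORTION_METRICS.items():
        m1, m2 = mask_fn(ya, large_del_threshold, params), mask_fn(oa, large_del_threshold, params)
        res = two_proportion_test(int(m1.sum()), len(ya), int(m2.sum()), len(oa))
        rows.append((metric, getattr(sy, metric), getattr(so, metric), res))
    for metric, col in (("mean_del", "del_total"), ("mean_ins", "insertion_len")):
        v1 = ya.loc[ya[col] >= 1, col].to_numpy(dtype=float)
        v2 = oa.loc[oa[col] >= 1, col].to_numpy(dtype=float)
        if len(v1) >= 2 and len(v2) >= 2:
            res = unpaired_t_test(v1, v2)
        else:
            res = None
        rows.append((metric, getattr(sy, metric), getattr(so, metric), res))
    table = pd.DataFrame(
        {
            "metric": [r[0] for r in rows],
            labels[0]: [r[1] for r in rows],
            labels[1]: [r[2] for r in rows],
            "statistic": [r[3].statistic if r[3] else np.nan for r in rows],
            "p_value": [r[3].p_value if r[3] else np.nan for r in rows],
            "method": [r[3].method if r[3] else "" for r in rows],
        }
    )
    pvals = table["p_value"].to_numpy()
    if bh_correct:
        adj = _benjamini_hochberg(pvals)
        table["p_adjusted"] = adj
        table["significant"] = adj < alpha
    else:
        table["significant"] = pvals < alpha
    return table


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv)
        ranked = pv[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        adj[ok] = out
    return adj


def read_facs_table(path) -> list[FacsCounts]:
    """Read a FACS count TSV with columns sample, n_total, n_gfp, n_dsred."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "n_gfp", "n_dsred"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FACS table missing columns: {sorted(missing)}")
    return [
        FacsCounts(
            sample=str(r.sample),
            n_gfp=int(r.n_gfp),
            n_dsred=int(r.n_dsred),
            n_total=int(getattr(r, "n_total", 20_000)),
        )
        for r in df.itertuples(index=False)
    ]
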