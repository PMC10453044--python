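"""Stem water-soluble-carbohydrate remobilisation statistics.

Remobilisation over the post-anthesis window [t_start, t_end] (default
12 to 22 days after anthesis, peak to permanent wilting point under
water deficit) is summarised two ways, because published summaries mix
the units:

    decline = WSC(t_start) - WSC(t_end)              [%dw]
    rate    = decline / (t_end - t_start)            [%dw day^-1]

The slowdown of a line relative to the parent is
(parent_decline - line_decline) / parent_decline * 100, identical on
either unit scale.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .types import RemobilisationResult, WSCSeries


def find_peak(series: WSCSeries | Mapping[int, float]) -> int:
    """DAA at which stem WSC is maximal; ties break to the earliest DAA."""
    obs = series.observations if isinstance(series, WSCSeries) else series
    if len(obs) < 2:
        raise ValueError("need at least two observations to locate a peak")
    return max(sorted(obs), key=lambda d: (obs[d], -d))


def remobilisation(
    series: WSCSeries | Mapping[int, float],
    t_start: int = 12,
    t_end: int = 22,
    line: str = "",
) -> RemobilisationResult:
    """Decline and per-day rate of stem WSC over the window."""
    obs = series.observations if isinstance(series, WSCSeries) else series
    if isinstance(series, WSCSeries) and not line:
        line = series.line
    for t in (t_start, t_end):
        if t not in obs:
            raise ValueError(f"no WSC observation at {t} DAA")
    if t_end <= t_start:
        raise ValueError("t_end must be after t_start")
    decline = obs[t_start] - obs[t_end]
    return RemobilisationResult(
        line=line,
        t_start=t_start,
        t_end=t_end,
        decline=decline,
        rate=decline / (t_end - t_start),
    )


def relative_slowdown(
    line_result: RemobilisationResult, parent_result: RemobilisationResult
) -> Optional[float]:
    """Percent by which a line remobilises less than the parent.

    None when the parent decline is not positive (undefined baseline).
    """
    if parent_result.decline <= 0:
        return None
    return (parent_result.decline - line_result.decline) / parent_result.decline * 100.0


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# phenotype-table driver


def series_from_table(
    pheno: pd.DataFrame, line: str, treatment: str, agg: str = "mean"
) -> WSCSeries:
    """Line x treatment WSC series from a tidy phenotype table
    (columns line, treatment, daa, stem_wsc_pct_dw[, grain_weight_g])."""
    sub = pheno[(pheno["line"] == line) & (pheno["treatment"] == treatment)]
    if sub.empty:
        raise ValueError(f"no phenotype rows for line={line!r} treatment={treatment!r}")
    obs = sub.groupby("daa")["stem_wsc_pct_dw"].agg(agg).to_dict()
    grain: dict[int, float] = {}
    if "grain_weight_g" in sub.columns:
        g = pd.to_numeric(sub["grain_weight_g"], errors="coerce")
        valid = sub.assign(_g=g).dropna(subset=["_g"])
        if not valid.empty:
            grain = valid.groupby("daa")["_g"].agg(agg).to_dict()
    return WSCSeries(line=line, treatment=treatment, observations=obs, grain_weight=grain)


def wsc_report(
    pheno: pd.DataFrame,
    parent_line: str,
    treatment: str = "water_deficit",
    t_start: int = 12,
    t_end: int = 22,
) -> pd.DataFrame:
    """Per-line remobilisation summary against the parent.

    Columns: line, peak_daa, wsc_start, wsc_end, decline_pct_dw,
    rate_pct_dw_per_day, slowdown_vs_parent_pct.
    """
    lines = sorted(pheno.loc[pheno["treatment"] == treatment, "line"].unique())
    if parent_line not in lines:
        raise ValueError(f"parent line {parent_line!r} absent from phenotype table")
    results = {}
    peaks = {}
    for line in lines:
        series = series_from_table(pheno, line, treatment)
        results[line] = remobilisation(series, t_start, t_end)
        peaks[line] = find_peak(series)
    parent = results[parent_line]
    rows = []
    for line in lines:
        res = results[line]
        slow = relative_slowdown(res, parent)
        series = series_from_table(pheno, line, treatment)
        rows.append(
            {
                "line": line,
                "peak_daa": peaks[line],
                "wsc_start": series.observations[t_start],
                "wsc_end": series.observations[t_end],
                "decline_pct_dw": res.decline,
                "rate_pct_dw_per_day": res.rate,
                "slowdown_vs_parent_pct": slow,
            }
        )
    return pd.DataFrame(rows)


def grain_remobilisation_correlation(
    pheno: pd.DataFrame,
    treatment: str = "water_deficit",
    t_start: int = 12,
    t_end: int = 22,
    grain_daa: int = 32,
) -> tuple[float, float, int]:
    """Pearson correlation of per-plant grain weight with per-plant
    remobilisation rate. Returns (r, p, n)."""
    sub = pheno[pheno["treatment"] == treatment].copy()
    sub["grain_weight_g"] = pd.to_numeric(sub["grain_weight_g"], errors="coerce")
    xs, ys = [], []
    for (_line, rep), grp in sub.groupby(["line", "replicate"]):
        by_daa = grp.set_index("daa")
        if t_start not in by_daa.index or t_end not in by_daa.index:
            continue
        grain = by_daa.loc[[grain_daa]]["grain_weight_g"].dropna() if grain_daa in by_daa.index else None
        if grain is None or grain.empty:
            continue
        rate = (
            float(by_daa.loc[t_start, "stem_wsc_pct_dw"])
            - float(by_daa.loc[t_end, "stem_wsc_pct_dw"])
        ) / (t_end - t_start)
        xs.append(float(grain.iloc[0]))
        ys.append(rate)
    r, p = correlate(xs, ys)
    return r, p, len(xs)
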