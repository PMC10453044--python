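"""Cluster-shift deletion calling.

A marker tracks a deletion when the mutant's cluster position has moved
relative to the euploid parent by at least 0.1 on the NormTheta axis or
0.5 on the NormR axis (a disjunction; ties at the threshold count). The
average position of a panel of unrelated mutant lines serves as a second
reference, and markers at which the two parent seed stocks ("biotypes")
disagree are excluded from deletion evidence. A probe whose only
hybridisation site is deleted loses all fluorescence ("null" allele),
which also pins the affected subgenome; an F1 backcross confirms a
deletion when its cluster sits between — and near the midpoint of — the
parent and mutant clusters (heterozygous dosage).
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    CallerConfig,
    ClusterShift,
    DeletionCall,
    IntensityObservation,
    MarkerRecord,
    theta_defined,
)


def compute_shift(
    reference_obs: IntensityObservation,
    sample_obs: IntensityObservation,
    reference: str = "parent",
) -> ClusterShift:
    """Signed cluster shift, reference minus sample on both axes.

    d_theta is NaN when either theta is undefined; d_r is always defined.
    """
    if reference_obs.marker_name != sample_obs.marker_name:
        raise ValueError(
            f"marker mismatch: {reference_obs.marker_name} vs {sample_obs.marker_name}"
        )
    if theta_defined(reference_obs.norm_theta) and theta_defined(sample_obs.norm_theta):
        d_theta = reference_obs.norm_theta - sample_obs.norm_theta
    else:
        d_theta = math.nan
    return ClusterShift(
        marker_name=sample_obs.marker_name,
        reference=reference,
        d_theta=d_theta,
        d_r=reference_obs.norm_r - sample_obs.norm_r,
    )


def panel_average(
    observations: Sequence[IntensityObservation], marker_name: str
) -> IntensityObservation:
    """Mean cluster position of the unrelated-mutant panel at one marker.

    Theta is averaged over panel members with defined theta; R over all
    members. With no defined theta the average is itself undefined.
    """
    obs = [o for o in observations if o.marker_name == marker_name]
    if not obs:
        raise ValueError(f"no panel observations for marker {marker_name}")
    thetas = [o.norm_theta for o in obs if theta_defined(o.norm_theta)]
    mean_theta = sum(thetas) / len(thetas) if thetas else math.nan
    mean_r = sum(o.norm_r for o in obs) / len(obs)
    return IntensityObservation("AV_HIB", marker_name, mean_theta, mean_r)


def _exceeds(shift: ClusterShift, config: CallerConfig) -> bool:
    theta_hit = theta_defined(shift.d_theta) and abs(shift.d_theta) >= config.theta_threshold
    return theta_hit or abs(shift.d_r) >= config.r_threshold


def flag_marker(
    shift_vs_parent: ClusterShift,
    shift_vs_panel: Optional[ClusterShift],
    config: CallerConfig,
) -> bool:
    """Putative-deletion flag: threshold disjunction against the parent,
    optionally required to hold against the panel average as well."""
    flagged = _exceeds(shift_vs_parent, config)
    if flagged and config.require_panel_concordance and shift_vs_panel is not None:
        flagged = _exceeds(shift_vs_panel, config)
    return flagged


def detect_null(sample_obs: IntensityObservation, null_floor: float) -> bool:
    """Null allele: total fluorescence below the floor."""
    return sample_obs.norm_r < null_floor


def confirm_het(
    parent_obs: IntensityObservation,
    mutant_obs: IntensityObservation,
    f1_obs: IntensityObservation,
    het_tolerance: float,
) -> Optional[bool]:
    """Heterozygous (backcross) confirmation at one marker.

    True when the F1 theta lies strictly between parent and mutant and
    within ``het_tolerance`` of their midpoint; None (indeterminate) when
    any theta is undefined.
    """
    tp, tm, tf = parent_obs.norm_theta, mutant_obs.norm_theta, f1_obs.norm_theta
    if not (theta_defined(tp) and theta_defined(tm) and theta_defined(tf)):
        return None
    lo, hi = min(tp, tm), max(tp, tm)
    if not lo < tf < hi:
        return False
    return abs(tf - (tp + tm) / 2.0) <= het_tolerance


def assign_subgenome(
    calls: Sequence[DeletionCall], markers: Sequence[MarkerRecord]
) -> tuple[Optional[str], list[str]]:
    """Attribute a candidate region to a subgenome via single-site nulls.

    Only a single-site probe is subgenome-specific: when deleted it goes
    null and names the subgenome directly. Returns (label, conflicts);
    the label is None when no single-site null exists or when nulls
    disagree (conflicts then lists the disagreeing subgenomes).
    """
    by_name = {m.name: m for m in markers}
    subs = []
    for call in calls:
        marker = by_name.get(call.marker_name)
        if marker is None or not marker.single_site:
            continue
        if call.status == "null":
            subs.append(marker.sites[0].subgenome)
    uniq = sorted(set(subs))
    if len(uniq) == 1:
        return uniq[0], []
    if len(uniq) > 1:
        return None, uniq
    return None, []


def exclude_biotype_markers(
    calls: Sequence[DeletionCall],
    parent_obs_hib_stock: Iterable[IntensityObservation],
    parent_obs_backcross_stock: Iterable[IntensityObservation],
    theta_threshold: float,
    r_threshold: float = math.inf,
) -> tuple[list[DeletionCall], list[str]]:
    """Drop markers at which the two parent seed stocks disagree.

    Different "biotypes" of the same cultivar genotype discordantly at
    some markers; against the wrong stock these mimic deletions in every
    mutant. A marker is excluded when the stocks' thetas differ by at
    least ``theta_threshold`` (or, if exactly one stock has no defined
    theta, when their R differ by ``r_threshold``). Returns the filtered
    calls (excluded ones retained but flagged ``excluded_biotype`` and
    demoted to status "none") and the biotype report list.
    """
    hib = {o.marker_name: o for o in parent_obs_hib_stock}
    bc = {o.marker_name: o for o in parent_obs_backcross_stock}
    report = []
    out = []
    for call in calls:
        a, b = hib.get(call.marker_name), bc.get(call.marker_name)
        discordant = False
        if a is not None and b is not None:
            if theta_defined(a.norm_theta) and theta_defined(b.norm_theta):
                discordant = abs(a.norm_theta - b.norm_theta) >= theta_threshold
            elif theta_defined(a.norm_theta) != theta_defined(b.norm_theta):
                discordant = abs(a.norm_r - b.norm_r) >= r_threshold
        if discordant:
            report.append(call.marker_name)
            out.append(
                DeletionCall(
                    marker_name=call.marker_name,
                    status="none",
                    flagged=call.flagged,
                    het_confirmed=call.het_confirmed,
                    subgenome=call.subgenome,
                    shift_parent=call.shift_parent,
                    shift_panel=call.shift_panel,
                    excluded_biotype=True,
                )
            )
        else:
            out.append(call)
    return out, report


# ---------------------------------------------------------------------------
# per-sample driver


def _pivot(intensities: pd.DataFrame, sample_id: str) -> dict[str, IntensityObservation]:
    sub = intensities[intensities["sample_id"] == sample_id]
    return {
        row.marker_name: IntensityObservation(
            sample_id, row.marker_name, float(row.norm_theta), float(row.norm_r)
        )
        for row in sub.itertuples(index=False)
    }


def call_sample(
    intensities: pd.DataFrame,
    markers: Sequence[MarkerRecord],
    parent_id: str,
    sample_id: str,
    f1_id: Optional[str] = None,
    panel_ids: Optional[Sequence[str]] = None,
    second_parent_id: Optional[str] = None,
    config: Optional[CallerConfig] = None,
) -> tuple[list[DeletionCall], list[str]]:
    """Call per-marker deletion evidence for one mutant sample.

    Markers with undefined theta in the parent are excluded from
    shift-based calling (a parent-null probe is uninformative); their R
    shift is still evaluated. Returns (calls, biotype_report); the report
    is empty unless ``second_parent_id`` provides the other seed stock.
    """
    config = config or CallerConfig()
    parent = _pivot(intensities, parent_id)
    if not parent:
        raise ValueError(f"parent sample {parent_id!r} not present in intensities")
    mutant = _pivot(intensities, sample_id)
    if not mutant:
        raise ValueError(f"sample {sample_id!r} not present in intensities")
    f1 = _pivot(intensities, f1_id) if f1_id else {}
    # panel average computed columnwise; matches panel_average() per marker
    av_theta: dict[str, float] = {}
    av_r: dict[str, float] = {}
    if panel_ids:
        panel_rows = intensities[intensities["sample_id"].isin(panel_ids)]
        grouped = panel_rows.groupby("marker_name")
        av_theta = grouped["norm_theta"].mean().to_dict()  # skips undefined thetas
        av_r = grouped["norm_r"].mean().to_dict()

    calls: list[DeletionCall] = []
    for marker in markers:
        p_obs = parent.get(marker.name)
        m_obs = mutant.get(marker.name)
        if p_obs is None or m_obs is None:
            continue
        shift_p = compute_shift(p_obs, m_obs, reference="parent")
        shift_av = None
        if marker.name in av_r:
            av = IntensityObservation(
                "AV_HIB", marker.name,
                av_theta.get(marker.name, math.nan)
                if not pd.isna(av_theta.get(marker.name, math.nan)) else math.nan,
                float(av_r[marker.name]),
            )
            shift_av = compute_shift(av, m_obs, reference="panel_average")
        flagged = flag_marker(shift_p, shift_av, config)
        is_null = (
            detect_null(m_obs, config.null_floor)
            and not detect_null(p_obs, config.null_floor)
        )
        status = "none"
        if flagged:
            status = "null" if is_null else "poly"
        het: Optional[bool] = None
        if marker.name in f1:
            het = confirm_het(p_obs, m_obs, f1[marker.name], config.het_tolerance)
        calls.append(
            DeletionCall(
                marker_name=marker.name,
                status=status,
                flagged=flagged,
                het_confirmed=het,
                subgenome=marker.sites[0].subgenome if marker.single_site else None,
                shift_parent=shift_p,
                shift_panel=shift_av,
            )
        )

    report: list[str] = []
    if second_parent_id is not None:
        second = _pivot(intensities, second_parent_id)
        calls, report = exclude_biotype_markers(
            calls,
            second.values(),
            parent.values(),
            theta_threshold=config.theta_threshold,
            r_threshold=config.r_threshold,
        )
    return calls, report


def calls_to_frame(calls: Sequence[DeletionCall]) -> pd.DataFrame:
    """Flatten calls into the output table dialect."""
    rows = []
    for c in calls:
        rows.append(
            {
                "marker_name": c.marker_name,
                "status": c.status,
                "flagged": c.flagged,
                "d_theta_parent": c.shift_parent.d_theta,
                "d_r_parent": c.shift_parent.d_r,
                "d_theta_panel": c.shift_panel.d_theta if c.shift_panel else math.nan,
                "d_r_panel": c.shift_panel.d_r if c.shift_panel else math.nan,
                "het_confirmed": c.het_confirmed,
                "subgenome": c.subgenome if c.subgenome else "",
                "excluded_biotype": c.excluded_biotype,
            }
        )
    return pd.DataFrame(rows)
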