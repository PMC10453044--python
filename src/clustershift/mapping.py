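"""Deletion interval mapping from flagged markers.

Flagged markers are grouped per chromosome into maximal runs whose
consecutive span_start gaps do not exceed ``gap_max``; a run with at
least ``min_markers`` members becomes a deletion interval bounded by its
flanking markers. Interval coordinates follow the flanking convention:
start = span_start of the first run marker, end = span_end of the last,
size = end - start (the plain difference — the published interval sizes
are exact differences of the printed flanking coordinates).
"""

from __future__ import annotations

import statistics
from typing import Optional, Sequence

from .calling import assign_subgenome
from .types import DeletionCall, DeletionInterval, MapperConfig, MarkerRecord, TrueDeletion


def default_gap_max(markers: Sequence[MarkerRecord]) -> int:
    """5x the median inter-marker span_start spacing (single chromosome)."""
    pos = sorted(m.span_start for m in markers)
    if len(pos) < 2:
        raise ValueError("need >= 2 markers to derive a gap threshold")
    gaps = [b - a for a, b in zip(pos, pos[1:])]
    return int(5 * statistics.median(gaps))


def median_spacing(markers: Sequence[MarkerRecord]) -> float:
    pos = sorted(m.span_start for m in markers)
    return statistics.median(b - a for a, b in zip(pos, pos[1:]))


def find_runs(
    flagged: Sequence[MarkerRecord],
    config: MapperConfig,
    all_markers: Optional[Sequence[MarkerRecord]] = None,
) -> list[list[MarkerRecord]]:
    """Maximal high-density runs of flagged markers on one chromosome.

    ``flagged`` must share a chromosome and be sorted by span_start.
    When ``config.gap_max`` is None it is derived from ``all_markers``
    (the full panel on that chromosome).
    """
    if not flagged:
        return []
    chroms = {m.chromosome for m in flagged}
    if len(chroms) > 1:
        raise ValueError(f"find_runs expects one chromosome, got {sorted(chroms)}")
    gap_max = config.gap_max
    if gap_max is None:
        gap_max = default_gap_max(all_markers if all_markers else flagged)
    runs: list[list[MarkerRecord]] = []
    current = [flagged[0]]
    for prev, m in zip(flagged, flagged[1:]):
        if m.span_start - prev.span_start <= gap_max:
            current.append(m)
        else:
            runs.append(current)
            current = [m]
    runs.append(current)
    return [r for r in runs if len(r) >= config.min_markers]


def make_interval(
    run: Sequence[MarkerRecord],
    config: MapperConfig,
    subgenome: Optional[str] = None,
    discordant: Sequence[MarkerRecord] = (),
) -> DeletionInterval:
    """Interval from a run's flanking markers."""
    if not run:
        raise ValueError("empty run")
    first, last = run[0], run[-1]
    start, end = first.span_start, last.span_end
    target = config.target_loci.get(first.chromosome)
    contains = bool(target) and start <= target[1] and target[0] <= end
    return DeletionInterval(
        chromosome=first.chromosome,
        start=start,
        end=end,
        flank_start_marker=first.name,
        flank_end_marker=last.name,
        n_support=len(run),
        subgenome=subgenome,
        contains_target=contains,
        discordant_markers=tuple(m.name for m in discordant),
        support_markers=tuple(m.name for m in run),
    )


def map_intervals(
    calls: Sequence[DeletionCall],
    markers: Sequence[MarkerRecord],
    config: Optional[MapperConfig] = None,
) -> list[DeletionInterval]:
    """Full mapping pass: calls -> per-chromosome deletion intervals.

    Biotype-excluded markers never contribute evidence. Unflagged
    markers lying between a run's flanks are recorded as discordant
    support (array probes can fail to shift when paralogous sites mask
    the dosage change) but do not split the run.
    """
    config = config or MapperConfig()
    flag_by_name = {c.marker_name: c for c in calls}
    by_chrom: dict[str, list[MarkerRecord]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    intervals: list[DeletionInterval] = []
    for chrom in sorted(by_chrom):
        chrom_markers = sorted(by_chrom[chrom], key=lambda m: (m.span_start, m.name))
        flagged = [
            m
            for m in chrom_markers
            if (c := flag_by_name.get(m.name)) is not None
            and c.flagged
            and not c.excluded_biotype
        ]
        for run in find_runs(flagged, config, all_markers=chrom_markers):
            inside = [
                m
                for m in chrom_markers
                if run[0].span_start <= m.span_start <= run[-1].span_start
            ]
            run_names = {m.name for m in run}
            discordant = [m for m in inside if m.name not in run_names]
            run_calls = [flag_by_name[m.name] for m in run]
            subgenome, _conflicts = assign_subgenome(run_calls, run)
            intervals.append(make_interval(run, config, subgenome, discordant))
    return intervals


def recover_truth(
    intervals: Sequence[DeletionInterval],
    true_deletions: Sequence[TrueDeletion],
    markers: Sequence[MarkerRecord],
) -> list[dict]:
    """Score mapped intervals against simulation ground truth.

    A true deletion counts as detected when an interval on the matching
    chromosome overlaps it (the mapped interval necessarily sits inside
    the deleted segment, since its flanking markers are deleted markers).
    Boundary error is the distance between mapped and true breakpoints at
    each end; subgenome_correct requires the single-site-null attribution
    to name the right subgenome.
    """
    report = []
    for td in true_deletions:
        hits = [
            iv
            for iv in intervals
            if iv.chromosome == td.subgenome and iv.overlaps(td.start, td.end)
        ]
        if hits:
            best = max(hits, key=lambda iv: min(iv.end, td.end) - max(iv.start, td.start))
            entry = {
                "subgenome": td.subgenome,
                "detected": True,
                "start_error": abs(best.start - td.start),
                "end_error": abs(best.end - td.end),
                "subgenome_correct": best.subgenome == td.subgenome,
                "interval": best,
            }
        else:
            entry = {
                "subgenome": td.subgenome,
                "detected": False,
                "start_error": None,
                "end_error": None,
                "subgenome_correct": False,
                "interval": None,
            }
        report.append(entry)
    return report
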