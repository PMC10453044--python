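"""File dialects: marker maps, intensity tables, calls, intervals, BED,
GFF3 genes, expression and phenotype tables, YAML configuration.

Position fields tolerate arbitrary digit-grouping separators (published
marker tables print coordinates like ``4,10,83,389``); every writer's
output round-trips byte-identically through its paired reader. Internal
coordinates are 1-based inclusive; the BED writer converts to 0-based
half-open.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import gffutils
import pandas as pd
import yaml

from .types import (
    DeletionInterval,
    GeneFeature,
    HybridisationSite,
    MarkerRecord,
    TrueDeletion,
)

PathLike = Union[str, Path]

_GROUPING = re.compile(r"[,\s._']")


def parse_position(text: str) -> int:
    """Parse a base-pair coordinate, stripping digit-grouping separators."""
    cleaned = _GROUPING.sub("", str(text).strip())
    if not cleaned.isdigit():
        raise ValueError(f"not a genomic position: {text!r}")
    return int(cleaned)


# ---------------------------------------------------------------------------
# marker map


def _format_site(site: HybridisationSite) -> str:
    base = f"{site.subgenome}:{site.position}:{site.allele}"
    return base if site.gain == 1.0 else f"{base}:{site.gain:g}"


def _parse_site(text: str, line_no: int) -> HybridisationSite:
    parts = text.split(":")
    if len(parts) not in (3, 4):
        raise ValueError(f"line {line_no}: malformed site string {text!r}")
    sub, pos, allele = parts[0], parse_position(parts[1]), parts[2]
    gain = float(parts[3]) if len(parts) == 4 else 1.0
    try:
        return HybridisationSite(subgenome=sub, position=pos, allele=allele, gain=gain)
    except ValueError as exc:
        raise ValueError(f"line {line_no}: {exc}") from exc


def read_marker_map(path: PathLike) -> list[MarkerRecord]:
    """Read a marker map CSV (snp_index,name,chromosome,span_start,
    span_end,sites with ';'-delimited site encoding)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"snp_index", "name", "chromosome", "span_start", "span_end", "sites"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing marker-map columns {sorted(missing)}")
    markers = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.name in seen:
            raise ValueError(f"{path} line {i}: duplicate marker name {row.name!r}")
        seen.add(row.name)
        if not row.sites.strip():
            raise ValueError(f"{path} line {i}: empty sites field for {row.name!r}")
        sites = tuple(_parse_site(s, i) for s in row.sites.split(";"))
        markers.append(
            MarkerRecord(
                snp_index=int(row.snp_index),
                name=row.name,
                chromosome=row.chromosome,
                span_start=parse_position(row.span_start),
                span_end=parse_position(row.span_end),
                sites=sites,
            )
        )
    return markers


def write_marker_map(markers: Sequence[MarkerRecord], path: PathLike) -> None:
    rows = [
        {
            "snp_index": m.snp_index,
            "name": m.name,
            "chromosome": m.chromosome,
            "span_start": m.span_start,
            "span_end": m.span_end,
            "sites": ";".join(_format_site(s) for s in m.sites),
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# intensity table


def read_intensities(path: PathLike) -> pd.DataFrame:
    """Intensity CSV: sample_id,marker_name,norm_theta,norm_r; an empty
    norm_theta field is the undefined-theta (no-signal) sentinel NaN."""
    df = pd.read_csv(
        path, dtype={"sample_id": str, "marker_name": str},
    )
    required = {"sample_id", "marker_name", "norm_theta", "norm_r"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing intensity columns {sorted(missing)}")
    df["norm_theta"] = pd.to_numeric(df["norm_theta"], errors="coerce")
    df["norm_r"] = pd.to_numeric(df["norm_r"])
    return df


def write_intensities(df: pd.DataFrame, path: PathLike) -> None:
    out = df.copy()
    out["norm_theta"] = out["norm_theta"].map(
        lambda t: "" if (t is None or (isinstance(t, float) and math.isnan(t))) else repr(float(t))
    )
    out["norm_r"] = out["norm_r"].map(lambda r: repr(float(r)))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# truth record


def write_truth(truth: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_truth(path: PathLike) -> dict:
    truth = json.loads(Path(path).read_text())
    truth["deletions"] = {
        sid: [TrueDeletion(**d) for d in dels]
        for sid, dels in truth.get("deletions", {}).items()
    }
    return truth


# ---------------------------------------------------------------------------
# calls / intervals


def write_calls(calls_frame: pd.DataFrame, path: PathLike) -> None:
    calls_frame.to_csv(path, index=False)


def read_calls(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"marker_name": str, "subgenome": str})
    df["subgenome"] = df["subgenome"].fillna("")
    return df


def intervals_to_frame(intervals: Sequence[DeletionInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": iv.chromosome,
                "start": iv.start,
                "end": iv.end,
                "size": iv.size,
                "flank_start_marker": iv.flank_start_marker,
                "flank_end_marker": iv.flank_end_marker,
                "n_support": iv.n_support,
                "subgenome": iv.subgenome or "",
                "contains_target": iv.contains_target,
                "support_markers": ";".join(iv.support_markers),
                "discordant_markers": ";".join(iv.discordant_markers),
            }
            for iv in intervals
        ],
        columns=[
            "chromosome", "start", "end", "size", "flank_start_marker",
            "flank_end_marker", "n_support", "subgenome", "contains_target",
            "support_markers", "discordant_markers",
        ],
    )


def write_intervals(intervals: Sequence[DeletionInterval], path: PathLike) -> None:
    intervals_to_frame(intervals).to_csv(path, index=False)


def read_intervals(path: PathLike) -> list[DeletionInterval]:
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DeletionInterval(
                chromosome=row.chromosome,
                start=parse_position(row.start),
                end=parse_position(row.end),
                flank_start_marker=row.flank_start_marker,
                flank_end_marker=row.flank_end_marker,
                n_support=int(row.n_support),
                subgenome=row.subgenome or None,
                contains_target=str(row.contains_target) == "True",
                support_markers=tuple(s for s in row.support_markers.split(";") if s),
                discordant_markers=tuple(s for s in row.discordant_markers.split(";") if s),
            )
        )
    return out


def write_bed(intervals: Sequence[DeletionInterval], path: PathLike) -> None:
    """BED export: 0-based half-open, so start-1/end from 1-based inclusive."""
    lines = [
        f"{iv.chromosome}\t{iv.start - 1}\t{iv.end}\tdeletion_{i + 1}\t{iv.n_support}\t."
        for i, iv in enumerate(intervals)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# GFF3 genes


def read_gff3_genes(
    path: PathLike,
    feature_types: Sequence[str] = ("gene",),
    confidence_key: str = "confidence",
    description_keys: Sequence[str] = ("description", "Note", "product"),
) -> list[GeneFeature]:
    """Load gene features from a GFF3 file (via gffutils, in-memory DB)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            desc = ""
            for key in description_keys:
                if key in feat.attributes:
                    desc = feat.attributes[key][0]
                    break
            confidence = feat.attributes.get(confidence_key, ["HC"])[0]
            genes.append(
                GeneFeature(
                    gene_id=feat.id,
                    chromosome=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    confidence=confidence,
                    description=desc,
                )
            )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def write_gff3_genes(genes: Sequence[GeneFeature], path: PathLike) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};confidence={g.confidence}"
        if g.description:
            attrs += f";description={g.description}"
        lines.append(
            f"{g.chromosome}\tclustershift\tgene\t{g.start}\t{g.end}\t.\t+\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression / phenotype


def read_expression(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample": str, "stage": str})
    required = {"gene_id", "sample", "stage", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expression columns {sorted(missing)}")
    df["tpm"] = pd.to_numeric(df["tpm"])
    return df


def write_expression(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotype(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"line": str, "treatment": str})
    required = {"line", "treatment", "daa", "stem_wsc_pct_dw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    df["daa"] = df["daa"].astype(int)
    df["stem_wsc_pct_dw"] = pd.to_numeric(df["stem_wsc_pct_dw"])
    return df


def write_phenotype(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML config


def load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def dump_yaml(data: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
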