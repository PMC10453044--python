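"""Gene content of deletion intervals.

Overlap queries run against an interval tree per chromosome (1-based
inclusive coordinates; a single shared base pair counts as overlap).
Functional classes come from an ordered keyword rule list seeded with the
four classes used to summarise the deleted segments (hydrolase, ligase,
oxidoreductase, transferase); non-target genes can additionally be
screened for negligible expression relative to a reference gene.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import DeletionInterval, GeneFeature

#: Ordered (class, keywords) rules applied to lower-cased descriptions;
#: first match wins. "exohydrolase" etc. match by substring.
DEFAULT_CLASS_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("hydrolase", ("hydrolase", "glycosidase", "peptidase", "protease",
                   "nuclease", "esterase", "phosphatase", "amylase")),
    ("ligase", ("ligase", "synthetase")),
    ("oxidoreductase", ("oxidoreductase", "dehydrogenase", "oxidase",
                        "reductase", "peroxidase", "cytochrome p450")),
    ("transferase", ("transferase", "kinase", "polymerase")),
)


class GeneIndex:
    """Per-chromosome interval tree over gene features."""

    def __init__(self, genes: Sequence[GeneFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            # half-open tree coordinates; +1 keeps 1-based inclusive semantics
            self._trees.setdefault(g.chromosome, IntervalTree()).addi(
                g.start, g.end + 1, g
            )

    def query(self, chromosome: str, start: int, end: int) -> list[GeneFeature]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)


def genes_in_interval(
    interval: DeletionInterval,
    annotation: Sequence[GeneFeature] | GeneIndex,
    hc_only: bool = False,
) -> list[GeneFeature]:
    """Genes overlapping a deletion interval by >= 1 bp, sorted by start.

    An unknown chromosome yields an empty list (the caller is warned via
    the pipeline log rather than an exception, since annotations often
    cover only part of an assembly).
    """
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)
    hits = index.query(interval.chromosome, interval.start, interval.end)
    if hc_only:
        hits = [g for g in hits if g.confidence == "HC"]
    return hits


def classify_function(
    gene: GeneFeature,
    rules: Sequence[tuple[str, Sequence[str]]] = DEFAULT_CLASS_RULES,
) -> str:
    """First-match keyword classification of a gene description.

    Empty or explicitly uncharacterised descriptions map to
    "uncharacterised"; anything unmatched maps to "other".
    """
    text = gene.description.strip().lower()
    if not text or "uncharacteri" in text or "unknown" in text:
        return "uncharacterised"
    for label, keywords in rules:
        if any(kw in text for kw in keywords):
            return label
    return "other"


def negligible_expression(
    gene_id: str,
    reference_gene_id: str,
    table: pd.DataFrame,
    stage: Optional[str] = None,
    ratio_threshold: float = 0.1,
) -> bool:
    """Expression-negligibility screen against a reference gene.

    True when the gene's maximum abundance over the (optionally
    stage-filtered) samples is below ``ratio_threshold`` times the
    reference's maximum over the same samples. A gene absent from the
    table counts as unexpressed; an absent reference is an error.
    """
    sub = table if stage is None else table[table["stage"] == stage]
    ref = sub[sub["gene_id"] == reference_gene_id]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene_id!r} absent from expression table")
    ref_max = float(ref["tpm"].max())
    gene_rows = sub[sub["gene_id"] == gene_id]
    gene_max = float(gene_rows["tpm"].max()) if not gene_rows.empty else 0.0
    return gene_max < ratio_threshold * ref_max


def annotate_intervals(
    intervals: Sequence[DeletionInterval],
    genes: Sequence[GeneFeature],
    expression: Optional[pd.DataFrame] = None,
    reference_genes: Optional[Mapping[str, str]] = None,
    stage: Optional[str] = "reproductive",
    ratio_threshold: float = 0.1,
    hc_only: bool = False,
) -> pd.DataFrame:
    """Tabulate gene content (+class, +negligibility) of each interval.

    ``reference_genes`` maps chromosome -> reference gene id (the target
    isoform on that chromosome) for the expression screen; intervals on
    chromosomes without a reference skip the screen (flag left empty).
    """
    index = GeneIndex(genes)
    rows = []
    for iv in intervals:
        ref_id = (reference_genes or {}).get(iv.chromosome)
        for g in genes_in_interval(iv, index, hc_only=hc_only):
            negligible: Optional[bool] = None
            if expression is not None and ref_id is not None and g.gene_id != ref_id:
                negligible = negligible_expression(
                    g.gene_id, ref_id, expression, stage=stage,
                    ratio_threshold=ratio_threshold,
                )
            rows.append(
                {
                    "chromosome": iv.chromosome,
                    "interval_start": iv.start,
                    "interval_end": iv.end,
                    "gene_id": g.gene_id,
                    "gene_start": g.start,
                    "gene_end": g.end,
                    "confidence": g.confidence,
                    "functional_class": classify_function(g),
                    "description": g.description,
                    "negligible_expression": negligible,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "interval_start", "interval_end", "gene_id",
            "gene_start", "gene_end", "confidence", "functional_class",
            "description", "negligible_expression",
        ],
    )
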