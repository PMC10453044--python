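"""Core domain types for the cluster-shift deletion pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention); the BED
writer in :mod:`clustershift.io` converts to 0-based half-open on output.
An undefined NormTheta (no fluorescence in either channel) is represented
as ``math.nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

SUBGENOMES = ("6A", "6B", "6D")
ALLELES = ("A", "B")


def theta_defined(theta: float) -> bool:
    """True if a NormTheta value carries information (not the NaN sentinel)."""
    return not math.isnan(theta)


@dataclass(frozen=True)
class HybridisationSite:
    """One genomic locus a probe hybridises to.

    In allohexaploid wheat a single array probe commonly binds the
    homoeologous copies on the A, B and D subgenomes; each binding site
    contributes ``gain`` signal units per allele copy to the channel of
    its ``allele``.
    """

    subgenome: str
    position: int
    allele: str
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if self.allele not in ALLELES:
            raise ValueError(f"allele must be one of {ALLELES}, got {self.allele!r}")
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")


@dataclass(frozen=True)
class MarkerRecord:
    """An array probe: assembly span plus its 1-3 hybridisation sites."""

    snp_index: int
    name: str
    chromosome: str
    span_start: int
    span_end: int
    sites: tuple[HybridisationSite, ...]

    def __post_init__(self) -> None:
        if self.span_start > self.span_end:
            raise ValueError(f"{self.name}: span_start > span_end")
        if not 1 <= len(self.sites) <= 3:
            raise ValueError(f"{self.name}: markers carry 1-3 sites, got {len(self.sites)}")
        subs = [s.subgenome for s in self.sites]
        if len(set(subs)) != len(subs):
            raise ValueError(f"{self.name}: at most one site per subgenome")

    @property
    def single_site(self) -> bool:
        return len(self.sites) == 1


@dataclass(frozen=True)
class TrueDeletion:
    """Simulation ground truth: one deleted segment on one subgenome."""

    subgenome: str
    start: int
    end: int
    zygosity: str = "hom"  # "hom" -> dosage 0 inside, "het" -> dosage 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("deletion start must be < end")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be hom or het, got {self.zygosity!r}")

    def covers(self, subgenome: str, position: int) -> bool:
        return subgenome == self.subgenome and self.start <= position <= self.end


@dataclass
class SampleGenome:
    """Per-sample allele-copy state.

    ``dosage`` maps (subgenome, position) to remaining copies of a site
    (euploid = 2); ``biotype_overrides`` lists marker names at which this
    sample's stock carries the swapped allele relative to the progenitor.
    """

    sample_id: str
    role: str  # parent | parent_alt_stock | mutant | backcross_f1 | panel
    deletions: tuple[TrueDeletion, ...] = ()
    biotype_overrides: frozenset = frozenset()

    def dosage_at(self, subgenome: str, position: int) -> int:
        for d in self.deletions:
            if d.covers(subgenome, position):
                return 0 if d.zygosity == "hom" else 1
        return 2


@dataclass
class SimConfig:
    """Conditions of a simulated array experiment.

    Defaults emulate the study design: one euploid parent genotyped from
    the backcross seed stock, a second parent sample from the mutagenised
    stock, one or more heavy-ion mutants with homozygous deletions, one F1
    backcross per mutant (heterozygous for the same deletion), and a panel
    of 96 unrelated mutagenised lines used as an averaged reference.
    """

    n_markers: int = 300
    multi_site_fraction: float = 0.7
    three_site_fraction: float = 2.0 / 3.0  # P(3 sites | multi-site)
    noise_sd: float = 0.05
    null_floor: float = 0.2
    seed: int = 0
    deletions: dict[str, list[TrueDeletion]] = field(default_factory=dict)
    biotype_rate: float = 0.0
    n_panel: int = 96
    chrom_length: int = 100_000_000
    homoeo_jitter: int = 5_000
    parent_id: str = "Chara"
    hib_stock_id: str = "Chara_hib_stock"

    def __post_init__(self) -> None:
        for name, p in (
            ("multi_site_fraction", self.multi_site_fraction),
            ("three_site_fraction", self.three_site_fraction),
            ("biotype_rate", self.biotype_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        for sample, dels in self.deletions.items():
            for d in dels:
                if d.end > self.chrom_length:
                    raise ValueError(
                        f"deletion {d} for {sample} extends beyond chromosome "
                        f"length {self.chrom_length}"
                    )


@dataclass(frozen=True)
class IntensityObservation:
    """NormTheta/NormR polar intensity of one sample at one marker."""

    sample_id: str
    marker_name: str
    norm_theta: float  # in [0, 1], or NaN when no signal in either channel
    norm_r: float

    def __post_init__(self) -> None:
        if self.norm_r < 0:
            raise ValueError("norm_r must be >= 0")
        if theta_defined(self.norm_theta) and not 0.0 <= self.norm_theta <= 1.0:
            raise ValueError(f"norm_theta out of [0,1]: {self.norm_theta}")


@dataclass(frozen=True)
class ClusterShift:
    """Signed shift of a sample's cluster position relative to a reference,
    computed as reference minus sample on both polar axes."""

    marker_name: str
    reference: str  # "parent" or "panel_average"
    d_theta: float  # NaN when either theta is undefined
    d_r: float


@dataclass
class CallerConfig:
    """Thresholds of the deletion caller.

    theta_threshold / r_threshold are the published flagging cut-offs
    (0.1 on NormTheta, 0.5 on NormR, as a disjunction). het_tolerance
    bounds the distance of the F1 cluster from the parent/mutant theta
    midpoint; exact halfway does not hold under the dosage model, so a
    small tolerance is required.
    """

    theta_threshold: float = 0.1
    r_threshold: float = 0.5
    null_floor: float = 0.2
    het_tolerance: float = 0.05
    require_panel_concordance: bool = True

    def __post_init__(self) -> None:
        if min(self.theta_threshold, self.r_threshold, self.null_floor) <= 0:
            raise ValueError("caller thresholds must be > 0")


@dataclass
class DeletionCall:
    """Per-marker deletion evidence for one mutant sample."""

    marker_name: str
    status: str  # "poly" | "null" | "none"
    flagged: bool
    het_confirmed: Optional[bool]  # None when not evaluable
    subgenome: Optional[str]  # single-site marker's subgenome, else None
    shift_parent: ClusterShift
    shift_panel: Optional[ClusterShift] = None
    excluded_biotype: bool = False


@dataclass
class MapperConfig:
    """Run-segmentation settings for interval mapping.

    ``gap_max`` (bp) caps the distance between consecutive flagged markers
    inside one run; ``None`` means 5x the chromosome's median inter-marker
    spacing. ``target_loci`` maps chromosome -> (start, end) of a locus of
    interest for containment reporting.
    """

    gap_max: Optional[int] = None
    min_markers: int = 3
    target_loci: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gap_max is not None and self.gap_max <= 0:
            raise ValueError("gap_max must be > 0")
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")


@dataclass
class DeletionInterval:
    """A mapped deletion: flanking-marker coordinates and support.

    ``size`` follows the end-minus-start convention (plain difference of
    the last flanking marker's span_end and the first flanking marker's
    span_start, not +1).
    """

    chromosome: str
    start: int
    end: int
    flank_start_marker: str
    flank_end_marker: str
    n_support: int
    subgenome: Optional[str] = None
    contains_target: bool = False
    discordant_markers: tuple[str, ...] = ()
    support_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must be < end")

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class GeneFeature:
    """A gene model from the annotation."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    confidence: str = "HC"  # HC | LC
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    def overlaps(self, start: int, end: int) -> bool:
        """1-bp overlap under 1-based inclusive coordinates."""
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class RemobilisationResult:
    """Stem-WSC remobilisation over a fixed post-anthesis window.

    ``decline`` is WSC(t_start) - WSC(t_end) in %dw; ``rate`` is the same
    per day. Both are exposed because published summaries mix the two.
    """

    line: str
    t_start: int
    t_end: int
    decline: float
    rate: float


@dataclass(frozen=True)
class WSCSeries:
    """One line x treatment stem-WSC time course (DAA -> %dw)."""

    line: str
    treatment: str
    observations: Mapping[int, float]
    grain_weight: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.observations.values():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"WSC %dw out of [0,100]: {v}")
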