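"""Synthetic Infinium-style array experiments for allohexaploid wheat.

The generator emulates the signal structure that makes deletion calling
in a hexaploid non-trivial: a probe may hybridise to homoeologous loci on
up to three subgenomes (6A/6B/6D), so its two-channel intensity is a sum
over allele copies across those sites. Deleting one site shifts the
cluster along NormTheta and/or drops NormR; deleting the only site of a
single-site probe extinguishes fluorescence (a "null" allele).

Signal model
------------
For a probe with sites :math:`i` (allele :math:`a_i`, gain
:math:`\\gamma_i`) and per-site copy number :math:`d_i`:

.. math::

    X = \\sum_{a_i=A} \\gamma_i d_i + \\epsilon_X, \\qquad
    Y = \\sum_{a_i=B} \\gamma_i d_i + \\epsilon_Y

with channel noise :math:`\\epsilon \\sim N(0, \\sigma^2)` clamped at 0,
NormTheta :math:`= (2/\\pi)\\,\\mathrm{atan2}(Y, X)` and NormR
:math:`= X + Y`. This is the standard Infinium polar convention; with
per-allele gain 1 a euploid single-site probe sits at R = 2.

Sample design mirrors the study: a euploid parent genotyped from the
backcross seed stock, the mutagenised parent stock (a second "biotype" of
the same cultivar, differing by allele swaps at a small fraction of
markers), mutants with homozygous deletions, one F1 backcross per mutant
(heterozygous for the same deletion), and a 96-line panel of unrelated
mutagenised samples whose average is used as a second reference.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .types import (
    ALLELES,
    SUBGENOMES,
    GeneFeature,
    HybridisationSite,
    MarkerRecord,
    SampleGenome,
    SimConfig,
    TrueDeletion,
)

TWO_OVER_PI = 2.0 / math.pi


def _rngs(config: SimConfig) -> tuple[np.random.Generator, ...]:
    """Independent streams for panel construction, genotypes, noise and
    auxiliary fixtures, all derived from the single config seed."""
    seqs = np.random.SeedSequence(config.seed).spawn(4)
    return tuple(np.random.default_rng(s) for s in seqs)


# ---------------------------------------------------------------------------
# marker panel


def build_marker_panel(config: SimConfig) -> list[MarkerRecord]:
    """Build a marker panel across the three group-6 subgenomes.

    Markers are laid on a jittered regular grid per chromosome (so runs of
    deleted markers are never split by freak gaps), sorted by
    (chromosome, span_start). A ``multi_site_fraction`` of markers carry
    homoeologous sites on one or both other subgenomes at nearly identical
    coordinates; the remainder are single-site (subgenome-specific) probes.
    """
    rng = _rngs(config)[0]
    n = config.n_markers
    counts = {chrom: n // 3 for chrom in SUBGENOMES}
    for chrom in SUBGENOMES[: n % 3]:
        counts[chrom] += 1

    markers: list[MarkerRecord] = []
    snp_index = 0
    for chrom in SUBGENOMES:
        n_c = counts[chrom]
        if n_c == 0:
            continue
        spacing = config.chrom_length / n_c
        for i in range(n_c):
            pos = int((i + rng.uniform(0.1, 0.9)) * spacing) + 1
            pos = min(max(pos, 1), config.chrom_length)
            sites = [
                HybridisationSite(
                    subgenome=chrom,
                    position=pos,
                    allele=ALLELES[rng.integers(2)],
                )
            ]
            if rng.random() < config.multi_site_fraction:
                n_extra = 2 if rng.random() < config.three_site_fraction else 1
                others = [s for s in SUBGENOMES if s != chrom]
                rng.shuffle(others)
                for sub in others[:n_extra]:
                    jitter = int(rng.integers(-config.homoeo_jitter, config.homoeo_jitter + 1))
                    sites.append(
                        HybridisationSite(
                            subgenome=sub,
                            position=min(max(pos + jitter, 1), config.chrom_length),
                            allele=ALLELES[rng.integers(2)],
                        )
                    )
            snp_index += 1
            markers.append(
                MarkerRecord(
                    snp_index=snp_index,
                    name=f"synth_{chrom}_{i:04d}",
                    chromosome=chrom,
                    span_start=pos,
                    span_end=min(pos + 100, config.chrom_length),
                    sites=tuple(sites),
                )
            )
    markers.sort(key=lambda m: (m.chromosome, m.span_start, m.name))
    return markers


# ---------------------------------------------------------------------------
# signal


def signal(
    sites: Sequence[HybridisationSite],
    dosage: Mapping[tuple[str, int], int],
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Two-channel polar intensity of one probe under a dosage assignment.

    ``dosage`` maps (subgenome, position) to remaining allele copies; sites
    missing from the map are euploid (2 copies). Returns
    (norm_theta, norm_r); norm_theta is NaN when both channels are zero.
    """
    if not sites:
        raise ValueError("signal() requires at least one hybridisation site")
    x = 0.0
    y = 0.0
    for s in sites:
        d = dosage.get((s.subgenome, s.position), 2)
        if d not in (0, 1, 2):
            raise ValueError(f"dosage must be in {{0,1,2}}, got {d}")
        if s.allele == "A":
            x += s.gain * d
        else:
            y += s.gain * d
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        x = max(0.0, x + rng.normal(0.0, noise_sd))
        y = max(0.0, y + rng.normal(0.0, noise_sd))
    r = x + y
    theta = math.nan if (x == 0.0 and y == 0.0) else TWO_OVER_PI * math.atan2(y, x)
    return theta, r


# ---------------------------------------------------------------------------
# experiment


@dataclass
class SimResult:
    """Everything a simulated experiment produced."""

    config: SimConfig
    markers: list[MarkerRecord]
    samples: list[SampleGenome]
    intensities: pd.DataFrame  # sample_id, marker_name, norm_theta, norm_r
    truth: dict = field(default_factory=dict)


def _make_samples(config: SimConfig, swap_markers: frozenset) -> list[SampleGenome]:
    samples = [
        SampleGenome(config.parent_id, "parent", biotype_overrides=swap_markers),
        SampleGenome(config.hib_stock_id, "parent_alt_stock"),
    ]
    for sid in sorted(config.deletions):
        dels = tuple(config.deletions[sid])
        samples.append(SampleGenome(sid, "mutant", deletions=dels))
        het = tuple(
            TrueDeletion(d.subgenome, d.start, d.end, zygosity="het") for d in dels
        )
        samples.append(
            SampleGenome(f"{sid}_f1", "backcross_f1", deletions=het,
                         biotype_overrides=swap_markers)
        )
    for k in range(config.n_panel):
        samples.append(SampleGenome(f"HIB_{k + 1:03d}", "panel"))
    return samples


def simulate_experiment(config: SimConfig) -> SimResult:
    """Simulate a full array experiment with ground truth.

    The genotyped parent reference is the *backcross* seed stock: at
    biotype markers its alleles are swapped relative to the mutagenised
    stock the mutants and panel derive from, so those markers shift
    against every mutant — the artefact the biotype screen removes. F1
    samples carry one mutagenised-stock haplotype (with the mutant's
    deletion) and one backcross-stock haplotype.
    """
    _, rng_geno, rng_noise, _ = _rngs(config)
    markers = build_marker_panel(config)
    n_m = len(markers)

    swap = rng_geno.random(n_m) < config.biotype_rate
    swap_names = frozenset(m.name for m, s in zip(markers, swap) if s)
    # a full allele swap mirrors (X, Y) -> (Y, X); it is observable as a
    # stock discordance only where the euploid channels differ
    observable_swaps = []
    for m, s in zip(markers, swap):
        if not s:
            continue
        x0 = sum(2 * site.gain for site in m.sites if site.allele == "A")
        y0 = sum(2 * site.gain for site in m.sites if site.allele == "B")
        if x0 != y0:
            observable_swaps.append(m.name)
    samples = _make_samples(config, swap_names)

    # flat site arrays
    site_marker = []
    site_sub = []
    site_pos = []
    site_is_a = []
    site_gain = []
    for j, m in enumerate(markers):
        for s in m.sites:
            site_marker.append(j)
            site_sub.append(s.subgenome)
            site_pos.append(s.position)
            site_is_a.append(s.allele == "A")
            site_gain.append(s.gain)
    site_marker = np.asarray(site_marker)
    site_pos_arr = np.asarray(site_pos)
    site_is_a = np.asarray(site_is_a)
    site_gain = np.asarray(site_gain)
    site_swap = swap[site_marker]

    def deleted_mask(dels: Sequence[TrueDeletion], zyg: str) -> np.ndarray:
        mask = np.zeros(len(site_marker), dtype=bool)
        for d in dels:
            if d.zygosity != zyg:
                continue
            sub_match = np.asarray([s == d.subgenome for s in site_sub])
            mask |= sub_match & (site_pos_arr >= d.start) & (site_pos_arr <= d.end)
        return mask

    n_s = len(samples)
    X = np.zeros((n_s, n_m))
    Y = np.zeros((n_s, n_m))
    for k, sample in enumerate(samples):
        # copies from the mutagenised (hib) stock and the backcross stock
        if sample.role == "parent":
            hib = np.zeros(len(site_marker))
            bc = np.full(len(site_marker), 2.0)
        elif sample.role == "backcross_f1":
            hib = np.ones(len(site_marker))
            hib[deleted_mask(sample.deletions, "het")] = 0.0
            bc = np.ones(len(site_marker))
        else:  # parent_alt_stock, mutant, panel: pure hib stock
            hib = np.full(len(site_marker), 2.0)
            hib[deleted_mask(sample.deletions, "hom")] = 0.0
            hib[deleted_mask(sample.deletions, "het")] = 1.0
            bc = np.zeros(len(site_marker))
        carries_a = np.where(site_swap, ~site_is_a, site_is_a)
        a_copies = hib * site_is_a + bc * carries_a
        b_copies = hib * ~site_is_a + bc * ~carries_a
        X[k] = np.bincount(site_marker, weights=site_gain * a_copies, minlength=n_m)
        Y[k] = np.bincount(site_marker, weights=site_gain * b_copies, minlength=n_m)

    if config.noise_sd > 0:
        noise = rng_noise.normal(0.0, config.noise_sd, size=(n_s, n_m, 2))
        X = np.maximum(0.0, X + noise[:, :, 0])
        Y = np.maximum(0.0, Y + noise[:, :, 1])

    R = X + Y
    with np.errstate(invalid="ignore"):
        theta = TWO_OVER_PI * np.arctan2(Y, X)
    theta[(X == 0.0) & (Y == 0.0)] = np.nan

    marker_names = [m.name for m in markers]
    frames = pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in samples], n_m),
            "marker_name": np.tile(marker_names, n_s),
            "norm_theta": theta.ravel(),
            "norm_r": R.ravel(),
        }
    )
    truth = {
        "seed": config.seed,
        "parent_id": config.parent_id,
        "hib_stock_id": config.hib_stock_id,
        "deletions": {
            sid: [asdict(d) for d in dels] for sid, dels in sorted(config.deletions.items())
        },
        "f1_of": {f"{sid}_f1": sid for sid in sorted(config.deletions)},
        "biotype_markers": sorted(observable_swaps),
        "biotype_swap_markers_all": sorted(swap_names),
        "panel_ids": [s.sample_id for s in samples if s.role == "panel"],
        "roles": {s.sample_id: s.role for s in samples},
    }
    return SimResult(config, markers, samples, frames, truth)


# ---------------------------------------------------------------------------
# auxiliary fixtures: annotation and phenotype


_DESCRIPTION_POOL = (
    ("uncharacterised protein", 10),
    ("glycoside hydrolase family protein", 2),
    ("UDP-glycosyltransferase", 2),
    ("NADP-dependent oxidoreductase", 1),
    ("DNA ligase-like protein", 1),
    ("cytochrome P450 family protein", 2),
    ("F-box domain containing protein", 2),
)


def simulate_genes(
    config: SimConfig,
    gene_spacing: int = 400_000,
    gene_length: int = 3_000,
    target_loci: Optional[Mapping[str, tuple[int, int]]] = None,
) -> list[GeneFeature]:
    """Tile a synthetic gene annotation along each chromosome.

    Descriptions are drawn from a small pool spanning the functional
    classes of interest; if ``target_loci`` is given, a fructan
    1-exohydrolase gene is placed at each locus.
    """
    rng = _rngs(config)[3]
    pool = [d for d, w in _DESCRIPTION_POOL for _ in range(w)]
    genes: list[GeneFeature] = []
    for chrom in SUBGENOMES:
        i = 0
        start = gene_spacing // 2
        while start + gene_length <= config.chrom_length:
            i += 1
            genes.append(
                GeneFeature(
                    gene_id=f"SYNG{chrom}{i:05d}",
                    chromosome=chrom,
                    start=start,
                    end=start + gene_length - 1,
                    confidence="HC" if rng.random() < 0.8 else "LC",
                    description=pool[rng.integers(len(pool))],
                )
            )
            start += gene_spacing
    for chrom, (t_start, t_end) in (target_loci or {}).items():
        genes.append(
            GeneFeature(
                gene_id=f"FEH_{chrom}",
                chromosome=chrom,
                start=t_start,
                end=t_end,
                confidence="HC",
                description="Fructan 1-exohydrolase",
            )
        )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def simulate_expression(
    genes: Sequence[GeneFeature],
    config: SimConfig,
    stages: Sequence[str] = ("vegetative", "reproductive"),
    n_samples_per_stage: int = 2,
) -> pd.DataFrame:
    """Synthetic expression table (gene x sample, TPM-like).

    Target (1-FEH) genes are strongly expressed at the reproductive
    stage; most other genes are near-silent, with a small fraction given
    moderate expression so the negligibility screen has both outcomes.
    """
    rng = _rngs(config)[3]
    rng = np.random.default_rng(rng.integers(2**31))  # decouple from gene draw
    rows = []
    for g in genes:
        is_target = g.description.lower().startswith("fructan 1-exohydrolase")
        expressed = is_target or rng.random() < 0.05
        for stage in stages:
            for k in range(n_samples_per_stage):
                if is_target:
                    base = 50.0 if stage == "reproductive" else 8.0
                elif expressed:
                    base = 12.0
                else:
                    base = 0.2
                tpm = max(0.0, rng.normal(base, base * 0.15 + 0.02))
                rows.append((g.gene_id, f"{stage}_{k + 1}", stage, round(tpm, 3)))
    return pd.DataFrame(rows, columns=["gene_id", "sample", "stage", "tpm"])


def simulate_wsc(
    seed: int = 0,
    n_rep: int = 6,
    rho: float = 0.78,
    rate_sd: float = 0.35,
    wsc_sd: float = 1.2,
    lines: Sequence[str] = datasets.LINES,
) -> pd.DataFrame:
    """Per-replicate stem-WSC time courses and grain weights.

    Replicate curves scatter around the line-mean anchors; each
    water-deficit plant's grain weight at 32 DAA is generated so that its
    correlation with the plant's 12->22 DAA remobilisation rate is
    ``rho`` in expectation (grain weight responds linearly to the rate
    with noise sized from ``rho``).
    """
    rng = np.random.default_rng(seed)
    table = datasets.load_wsc_table()
    beta = 0.08  # g per (%dw/day)
    noise_g = beta * rate_sd * math.sqrt(1.0 / rho**2 - 1.0)
    rows = []
    for line in lines:
        for treatment in ("water_deficit", "well_watered"):
            mean_curve = (
                table[(table.line == line) & (table.treatment == treatment)]
                .set_index("daa")["stem_wsc_pct_dw"]
                .to_dict()
            )
            for rep in range(1, n_rep + 1):
                if treatment == "water_deficit":
                    # plant-level remobilisation rate drives both endpoints
                    mean_rate = (mean_curve[12] - mean_curve[22]) / 10.0
                    rate = mean_rate + rng.normal(0.0, rate_sd)
                    wsc12 = max(1.0, mean_curve[12] + rng.normal(0.0, wsc_sd))
                    wsc22 = max(0.0, wsc12 - 10.0 * rate)
                    grain = max(0.05, 0.55 + beta * rate + rng.normal(0.0, noise_g))
                else:
                    wsc12 = wsc22 = None
                    grain = max(0.05, 1.0 + rng.normal(0.0, 0.08))
                for daa, wsc in mean_curve.items():
                    if treatment == "water_deficit" and daa == 12:
                        val = wsc12
                    elif treatment == "water_deficit" and daa == 22:
                        val = wsc22
                    else:
                        val = max(0.0, wsc + rng.normal(0.0, wsc_sd))
                    rows.append(
                        (
                            line,
                            treatment,
                            daa,
                            round(float(val), 3),
                            round(float(grain), 4) if daa == 32 else "",
                            rep,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["line", "treatment", "daa", "stem_wsc_pct_dw", "grain_weight_g", "replicate"],
    )
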