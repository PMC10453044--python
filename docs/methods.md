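# Methods

## Problem

Heavy-ion bombardment (HIB) of allohexaploid wheat produces large
chromosomal deletions. Given Infinium-style SNP-array intensity exports
(NormTheta/NormR polar coordinates per sample x marker) for a euploid
parent cultivar, HIB mutant lines, parent x mutant F1 backcrosses and a
panel of unrelated HIB lines, the pipeline (i) flags markers whose
cluster position has shifted in a mutant, (ii) segments flagged markers
into deletion intervals bounded by flanking markers, (iii) lists and
classifies the genes inside each interval and screens non-target genes
for negligible expression, and (iv) summarises stem water-soluble
carbohydrate (WSC) remobilisation phenotypes of the mutant lines.

Hexaploidy is what makes this non-trivial: a single array probe often
hybridises to homoeologous loci on two or three subgenomes (6A/6B/6D),
so deleting one locus does not abolish the signal — it moves the cluster
part-way. Only a subgenome-specific (single-site) probe goes dark
("null" allele) when its locus is deleted, which is also what pins the
deletion to a subgenome.

## Signal model (synthetic data)

Per probe with hybridisation sites *i* (allele a_i in {A,B}, gain
gamma_i > 0) and per-site copy number d_i in {0,1,2}:

    X = sum_{a_i=A} gamma_i d_i + eps_X,   Y = sum_{a_i=B} gamma_i d_i + eps_Y
    NormTheta = (2/pi) atan2(Y, X),        NormR = X + Y

with eps ~ N(0, sigma^2) per channel, clamped at 0. NormTheta is
undefined (NaN, written as an empty CSV field) when both channels are
zero. This is the standard Infinium polar convention; the exporting
software's own normalisation is out of scope — the pipeline consumes
NormTheta/NormR as given.

Dosage states: euploid = 2 copies per site; homozygous deletion = 0;
F1 backcross of a homozygous mutant = 1 (the "HET" position roughly
midway between parent and mutant clusters). Exact theta-midpoint
equality does *not* hold under this model: for the canonical 3-site
probe (one A site on 6A, B sites on 6B/6D, gains 1) the euploid, F1 and
mutant thetas are 0.7048, 0.8440 and 1.0, an F1 offset of 0.0084 from
the midpoint; the worst case over site/allele configurations with unit
gains is a 2-site A/B probe at 0.0452. The HET tolerance default (0.05)
is chosen to cover exactly this model geometry.

### Generator defaults (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| markers | 300 (100 per chromosome) | enough density to span Mb-scale deletions with >= 3 markers |
| chromosome length | 1e8 bp | scaled down ~6x from wheat chromosome 6A; keeps marker spacing realistic in genetic terms |
| multi-site fraction | 0.7 | most transcriptome-derived probes hit homoeologues |
| P(3 sites \| multi-site) | 2/3 | homoeologue triads dominate retained wheat genes |
| per-site gain | 1.0 | unit-dosage scale; cluster positions then take a small set of exact rational-angle values |
| channel noise sigma | 0.05 | tight euploid clusters relative to the 0.1 theta threshold (theta s.d. 0.007-0.02 depending on R) |
| null floor | 0.2 | well below the single-site euploid R = 2, well above clamped noise |
| panel size | 96 | the unrelated-HIB reference panel of the study design |
| biotype rate | 0 (0.02 in the screen studies) | allele swaps in the backcross parent stock |

Marker positions sit on a jittered regular grid (uniform offset in
[0.1, 0.9] of the spacing) rather than a Poisson process, so a run of
deleted markers is never split by a freak gap; homoeologous sites of a
multi-site probe lie within +/-5 kb of the primary position on the
other subgenomes.

Biotypes: the genotyped "Chara" reference sample is the *backcross*
seed stock, while mutants, F1s and the panel derive from the mutagenised
stock; at a configurable fraction of markers the backcross stock carries
swapped alleles. Against the wrong stock these markers shift in *every*
mutant — the artefact the biotype screen removes. A full allele swap
mirrors (X, Y) to (Y, X), so it is observable only where X != Y; the
truth record lists observable swaps as `biotype_markers` (all drawn
swaps are kept under `biotype_swap_markers_all`). The F1 inherits one
haplotype from each stock, and the haplotype transmitted by a homozygous
mutant always carries the deletion.

What the generator does **not** emulate: raw two-colour intensities and
their normalisation, probe thermodynamics and cross-hybridisation
gradients, base substitutions and rearrangements from the irradiation,
segregation within biotype stocks, plate/batch effects. Passing the
recovery studies therefore shows the calling logic is correct under the
stated dosage model, not that the thresholds are optimal for any
particular real array chemistry.

## Deletion calling

Shift vs the euploid parent: d_theta = theta_ref - theta_sample,
d_r likewise (signed). A marker is flagged when |d_theta| >= 0.1 OR
|d_r| >= 0.5 (ties flag; both thresholds configurable). When a panel is
present the same disjunction must also hold against the panel average
(configurable, default on). A marker with undefined parent theta never
flags via theta, only via R; null = sample R below the null floor while
the parent has signal. HET confirmation at a marker requires the F1
theta strictly between parent and mutant and within the HET tolerance of
their midpoint; it is indeterminate (not false) when any theta is
undefined. Subgenome attribution of a candidate region uses single-site
null markers inside the region: one subgenome in consensus assigns it,
disagreement reports a conflict, absence leaves it unassigned.

The biotype screen removes markers at which the two parent stocks'
thetas differ by at least the theta threshold (or, when exactly one
stock is null, whose R differ by the R threshold); excluded markers are
demoted to status "none", listed in a report, and can never support or
flank an interval.

## Interval mapping

Per chromosome, flagged (non-excluded) markers form maximal runs with
consecutive span_start gaps <= gap_max (default 5x the chromosome's
median inter-marker spacing — no clustering rule is prescribed by the
source analysis, so this is a package choice); runs need >= 3 markers
(configurable, >= 2). Interval coordinates follow the flanking
convention: start = span_start of the first run marker, end = span_end
of the last, size = end - start as a plain difference (the published
interval sizes are exact differences of the printed flanking
coordinates, which fixes the convention; not end - start + 1).
Unflagged markers between the flanks are recorded as discordant support
but do not split a run (paralogous sites can mask a dosage change).
Breakpoints are never refined below marker resolution, and no
multi-sample joint segmentation is attempted.

Because flanking markers are themselves deleted markers, a mapped
interval sits *inside* the true deleted segment; the per-end boundary
error is bounded by the distance from the breakpoint to the nearest
informative marker, i.e. about one marker spacing.

## Annotation

Interval gene queries run on an interval tree per chromosome, 1-based
inclusive, with a 1-bp shared base counting as overlap (a brute-force
scan in 0-based half-open coordinates is kept as a test oracle).
Functional classes come from an ordered first-match keyword list over
gene descriptions (hydrolase, ligase, oxidoreductase, transferase, then
other/uncharacterised) — a pragmatic stand-in for curated protein
annotation, shipped as data so users can replace it. The expression
screen calls a gene negligible when its maximum abundance over the
stage-filtered samples is < 0.1x (configurable) the reference gene's
maximum over the same samples; a gene absent from the table counts as
unexpressed, an absent reference is an error.

## WSC remobilisation

Remobilisation over the window [12, 22] days after anthesis (peak to
permanent wilting point under water deficit; the window is a config
default, not hard-coded) is reported both as the decline
WSC(12) - WSC(22) in %dw and as the per-day rate decline/10, because
published summaries mix the two unit conventions. Relative slowdown vs
the parent is (parent_decline - line_decline)/parent_decline x 100.
Peaks tie-break to the earliest day. Pearson correlations (grain weight
vs remobilisation rate) use the standard product-moment estimator with
the t-based two-sided p-value; constant input yields an undefined r.
The built-in phenotype table anchors the published line means at the
peak and 22-DAA stages and fills the remaining stages with clearly
marked synthetic interpolations shaped only to preserve the anchored
peak positions; all headline statistics depend on anchors alone. Where
a published rounded summary disagrees with its own printed endpoints
(the parent line's decline, 25.2 vs 31.0 - 5.7 = 25.3), computed values
are reported without adjustment. Group-mean ANOVA/post-hoc machinery is
out of scope; means are reported descriptively.

## Validation studies (in `clustershift.validation`)

Raw data behind the original analysis are unavailable, so the caller is
accepted by construction-based properties, each summarised by
`scripts/acceptance.py` (problem sizes chosen as the package's study
conditions):

1. **Flag oracle** — 100 noise-free simulations (300 markers, random
   3 Mb homozygous 6A deletion): the flagged set must equal a
   closed-form brute-force prediction computed independently of the
   signal pipeline.
2. **Recovery** — 100 noisy simulations (900 markers, sigma 0.05): the
   mapped interval must overlap and sit inside the true deletion, with
   median boundary error below the median marker spacing.
3. **HET geometry** — noise-free F1 simulations (matching the regime in
   which the HET-ordering property is stated): every informative marker
   (flagged, multi-site, defined thetas, parent-mutant separation >= the
   theta threshold) must satisfy strict betweenness, and >= 95% must sit
   within the 0.05 midpoint tolerance — a check that the tolerance
   covers the dosage-model geometry. Betweenness under noise is
   exercised separately in the unit suite.
4. **Specificity** — 100 deletion-free noisy simulations: zero intervals.
5. **Biotype screen** — 100 noisy simulations with 2% observable stock
   swaps: no interval flank is ever a biotype marker.
6. **Annotation oracle** — 1000 random intervals against a 10-gene
   fixture: exact agreement with the brute-force overlap scan.
7. **Pearson calibration** — 1000 bivariate-normal datasets
   (rho = 0.78, n = 24): Monte-Carlo mean within 0.03 of rho (the small
   negative bias of r at n = 24 is ~0.006).

## Numerical notes and limitations

- Ties at thresholds flag (>=); threshold values never coincide with
  attainable noise-free shift values under unit gains, so oracle
  equality is float-robust.
- Undefined theta is NaN everywhere in memory and an empty field on
  disk; any comparison involving it is explicitly handled (never relies
  on NaN propagation through a threshold test).
- Determinism: every stochastic component takes a single integer seed;
  independent streams are spawned per purpose, so e.g. the marker panel
  for a given config seed is identical whether or not noise is drawn.
- The caller treats the 0.5 NormR criterion as an absolute difference
  (whether the original was absolute or relative to parent R is
  unstated).
- Deletions spanning a chromosome end, nested/overlapping deletions in
  one sample, and dosage states above 2 (duplications) are out of scope.
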