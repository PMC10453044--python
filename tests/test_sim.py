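"""Signal model and simulated-experiment behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from clustershift import sim
from clustershift.types import HybridisationSite, SimConfig, TrueDeletion

TWO_OVER_PI = 2.0 / math.pi


class TestSignal:
    @pytest.mark.parametrize(
        "sites, dosage, expected_theta, expected_r",
        [
            # single channel: all-A sites pin theta at 0
            ([("6A", 100, "A"), ("6B", 100, "A")], {}, 0.0, 4.0),
            # symmetric A/B euploid
            ([("6A", 100, "A"), ("6B", 100, "B")], {}, 0.5, 4.0),
            # 3-site A+B+B euploid: closed-form atan2(4, 2)
            (
                [("6A", 100, "A"), ("6B", 100, "B"), ("6D", 100, "B")],
                {},
                TWO_OVER_PI * math.atan2(4, 2),  # 0.704833
                6.0,
            ),
            # same probe with the 6A site homozygously deleted
            (
                [("6A", 100, "A"), ("6B", 100, "B"), ("6D", 100, "B")],
                {("6A", 100): 0},
                1.0,
                4.0,
            ),
            # heterozygous (backcross) dosage at the 6A site
            (
                [("6A", 100, "A"), ("6B", 100, "B"), ("6D", 100, "B")],
                {("6A", 100): 1},
                TWO_OVER_PI * math.atan2(4, 1),  # 0.844042
                5.0,
            ),
        ],
    )
    def test_closed_form(self, sites, dosage, expected_theta, expected_r):
        site_objs = [HybridisationSite(s, p, a) for s, p, a in sites]
        theta, r = sim.signal(site_objs, dosage)
        assert theta == pytest.approx(expected_theta, abs=1e-12)
        assert r == pytest.approx(expected_r, abs=1e-12)

    def test_all_sites_deleted_gives_null(self):
        site = HybridisationSite("6A", 100, "A")
        theta, r = sim.signal([site], {("6A", 100): 0})
        assert math.isnan(theta)
        assert r == 0.0

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            sim.signal([], {})

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            sim.signal([HybridisationSite("6A", 100, "A")], {("6A", 100): 3})

    @given(
        dosages=st.lists(st.integers(0, 2), min_size=2, max_size=3),
        alleles=st.lists(st.sampled_from("AB"), min_size=2, max_size=3),
        gains=st.lists(st.floats(0.2, 3.0), min_size=2, max_size=3),
    )
    def test_theta_bounded_r_nonnegative(self, dosages, alleles, gains):
        n = min(len(dosages), len(alleles), len(gains))
        subs = ["6A", "6B", "6D"][:n]
        sites = [
            HybridisationSite(s, 100, a, g)
            for s, a, g in zip(subs, alleles[:n], gains[:n])
        ]
        dosage = {(s.subgenome, 100): d for s, d in zip(sites, dosages[:n])}
        theta, r = sim.signal(sites, dosage)
        assert r >= 0.0
        if r > 0:
            assert 0.0 <= theta <= 1.0
        else:
            assert math.isnan(theta)

    def test_theta_monotone_in_deleted_site_dosage(self, three_site_marker):
        """Euploid/het/hom thetas at an affected multi-site probe are
        strictly ordered, with the heterozygote in between."""
        sites = three_site_marker.sites
        key = ("6A", sites[0].position)
        thetas = [sim.signal(sites, {key: d})[0] for d in (2, 1, 0)]
        assert thetas[0] < thetas[1] < thetas[2]


class TestMarkerPanel:
    def test_degenerate_single_marker(self):
        cfg = SimConfig(n_markers=1, multi_site_fraction=0.0, seed=0, n_panel=0)
        panel = sim.build_marker_panel(cfg)
        assert len(panel) == 1
        assert panel[0].single_site

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_markers=50, seed=42, n_panel=0)
        assert sim.build_marker_panel(cfg) == sim.build_marker_panel(cfg)

    def test_sorted_and_sites_on_distinct_subgenomes(self):
        cfg = SimConfig(n_markers=90, seed=5, n_panel=0)
        panel = sim.build_marker_panel(cfg)
        assert panel == sorted(panel, key=lambda m: (m.chromosome, m.span_start, m.name))
        for m in panel:
            subs = [s.subgenome for s in m.sites]
            assert len(set(subs)) == len(subs)
            assert 1 <= len(subs) <= 3

    def test_multi_site_fraction_within_binomial_bounds(self):
        n, p = 1000, 0.7
        cfg = SimConfig(n_markers=n, multi_site_fraction=p, seed=1, n_panel=0)
        panel = sim.build_marker_panel(cfg)
        k = sum(not m.single_site for m in panel)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= k <= hi


class TestSimulateExperiment:
    def test_no_deletion_no_noise_matches_parent_everywhere(self):
        cfg = SimConfig(n_markers=40, seed=2, n_panel=2, noise_sd=0.0,
                        deletions={"mut": []})
        res = sim.simulate_experiment(cfg)
        wide = res.intensities.pivot(index="marker_name", columns="sample_id",
                                     values="norm_r")
        for col in wide.columns:
            assert np.array_equal(wide[col].values, wide["Chara"].values)

    def test_three_site_marker_loses_one_third_of_r(self, small_deletion_config):
        res = sim.simulate_experiment(small_deletion_config)
        deletion = small_deletion_config.deletions["mut"][0]
        wide = res.intensities.pivot(index="marker_name", columns="sample_id",
                                     values="norm_r")
        hit = [
            m for m in res.markers
            if len(m.sites) == 3
            and any(deletion.covers(s.subgenome, s.position) for s in m.sites)
        ]
        assert hit, "fixture config must delete at least one 3-site marker"
        for m in hit:
            assert wide.loc[m.name, "mut"] == pytest.approx(
                wide.loc[m.name, "Chara"] * 2.0 / 3.0
            )

    def test_single_site_marker_in_deletion_goes_null(self, small_deletion_config):
        res = sim.simulate_experiment(small_deletion_config)
        deletion = small_deletion_config.deletions["mut"][0]
        wide_r = res.intensities.pivot(index="marker_name", columns="sample_id",
                                       values="norm_r")
        wide_t = res.intensities.pivot(index="marker_name", columns="sample_id",
                                       values="norm_theta")
        hit = [
            m for m in res.markers
            if m.single_site and deletion.covers(m.sites[0].subgenome, m.sites[0].position)
        ]
        assert hit
        for m in hit:
            assert wide_r.loc[m.name, "mut"] == 0.0
            assert math.isnan(wide_t.loc[m.name, "mut"])

    def test_unaffected_markers_conserved_across_samples(self, small_deletion_config):
        res = sim.simulate_experiment(small_deletion_config)
        deletion = small_deletion_config.deletions["mut"][0]
        untouched = [
            m.name for m in res.markers
            if not any(deletion.covers(s.subgenome, s.position) for s in m.sites)
        ]
        wide = res.intensities.pivot(index="marker_name", columns="sample_id",
                                     values="norm_r").loc[untouched]
        assert wide.nunique(axis=1).max() == 1

    def test_bit_identical_reruns(self, noisy_deletion_config):
        a = sim.simulate_experiment(noisy_deletion_config)
        b = sim.simulate_experiment(noisy_deletion_config)
        assert a.intensities.equals(b.intensities)
        assert a.truth == b.truth

    def test_f1_theta_between_parent_and_mutant(self, small_deletion_config):
        res = sim.simulate_experiment(small_deletion_config)
        deletion = small_deletion_config.deletions["mut"][0]
        wide = res.intensities.pivot(index="marker_name", columns="sample_id",
                                     values="norm_theta")
        for m in res.markers:
            if m.single_site:
                continue
            if not any(deletion.covers(s.subgenome, s.position) for s in m.sites):
                continue
            tp, tm, tf = wide.loc[m.name, ["Chara", "mut", "mut_f1"]]
            if abs(tp - tm) < 1e-9:
                continue
            assert min(tp, tm) < tf < max(tp, tm)

    def test_deletion_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                n_markers=10,
                deletions={"mut": [TrueDeletion("6A", 1, 200_000_000)]},
            )


class TestAuxGenerators:
    def test_genes_tiled_and_targets_inserted(self):
        cfg = SimConfig(n_markers=10, seed=3, chrom_length=5_000_000)
        genes = sim.simulate_genes(cfg, target_loci={"6B": (2_000_000, 2_003_000)})
        assert any(g.gene_id == "FEH_6B" for g in genes)
        by_chrom = {g.chromosome for g in genes}
        assert by_chrom == {"6A", "6B", "6D"}
        for g in genes:
            assert g.start <= g.end <= cfg.chrom_length

    def test_expression_reference_dominates_at_reproductive_stage(self):
        cfg = SimConfig(n_markers=10, seed=3, chrom_length=5_000_000)
        genes = sim.simulate_genes(cfg, target_loci={"6B": (2_000_000, 2_003_000)})
        expr = sim.simulate_expression(genes, cfg)
        rep = expr[expr.stage == "reproductive"]
        ref_max = rep[rep.gene_id == "FEH_6B"].tpm.max()
        assert ref_max > rep[rep.gene_id != "FEH_6B"].tpm.quantile(0.9)

    def test_wsc_generator_reproducible_and_anchored(self):
        a = sim.simulate_wsc(seed=9)
        b = sim.simulate_wsc(seed=9)
        assert a.equals(b)
        # line-mean peak stays at 12 DAA under water deficit
        deficit = a[(a.line == "Chara") & (a.treatment == "water_deficit")]
        means = deficit.groupby("daa")["stem_wsc_pct_dw"].mean()
        assert means.idxmax() == 12
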