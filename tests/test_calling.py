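"""Cluster-shift computation, flagging, null/HET detection, biotype screen."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from clustershift import calling, sim, validation
from clustershift.types import (
    CallerConfig,
    ClusterShift,
    DeletionCall,
    HybridisationSite,
    IntensityObservation,
    MarkerRecord,
)

TWO_OVER_PI = 2.0 / math.pi
THETA_EUPLOID = TWO_OVER_PI * math.atan2(4, 2)  # 0.704833
THETA_HET = TWO_OVER_PI * math.atan2(4, 1)  # 0.844042


def obs(sample, theta, r, marker="m"):
    return IntensityObservation(sample, marker, theta, r)


class TestComputeShift:
    def test_identity_is_zero(self):
        s = calling.compute_shift(obs("p", 0.5, 4.0), obs("m", 0.5, 4.0))
        assert s.d_theta == 0.0 and s.d_r == 0.0

    def test_three_site_deletion_example(self):
        """Parent at the 3-site euploid position, mutant with 6A deleted."""
        s = calling.compute_shift(obs("p", THETA_EUPLOID, 6.0), obs("m", 1.0, 4.0))
        assert s.d_theta == pytest.approx(-0.295167, abs=1e-6)
        assert s.d_r == pytest.approx(2.0)

    def test_marker_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calling.compute_shift(obs("p", 0.5, 4.0, "a"), obs("m", 0.5, 4.0, "b"))

    def test_undefined_theta_still_yields_r_shift(self):
        s = calling.compute_shift(obs("p", 0.3, 2.0), obs("m", math.nan, 0.0))
        assert math.isnan(s.d_theta)
        assert s.d_r == 2.0

    @given(
        tp=st.floats(0, 1), tm=st.floats(0, 1),
        rp=st.floats(0, 10), rm=st.floats(0, 10),
    )
    def test_antisymmetry(self, tp, tm, rp, rm):
        a = calling.compute_shift(obs("p", tp, rp), obs("m", tm, rm))
        b = calling.compute_shift(obs("m", tm, rm), obs("p", tp, rp))
        assert a.d_theta == -b.d_theta
        assert a.d_r == -b.d_r


class TestPanelAverage:
    def test_single_sample_passthrough(self):
        av = calling.panel_average([obs("h1", 0.4, 3.0)], "m")
        assert (av.norm_theta, av.norm_r) == (0.4, 3.0)
        assert av.sample_id == "AV_HIB"

    def test_mean_of_two(self):
        av = calling.panel_average([obs("h1", 0.4, 2.0), obs("h2", 0.6, 4.0)], "m")
        assert av.norm_theta == pytest.approx(0.5)
        assert av.norm_r == pytest.approx(3.0)

    def test_undefined_thetas_skipped(self):
        av = calling.panel_average(
            [obs("h1", math.nan, 0.0), obs("h2", 0.6, 4.0)], "m"
        )
        assert av.norm_theta == pytest.approx(0.6)
        assert av.norm_r == pytest.approx(2.0)

    def test_all_undefined_gives_undefined_mean(self):
        av = calling.panel_average([obs("h1", math.nan, 0.0)], "m")
        assert math.isnan(av.norm_theta) and av.norm_r == 0.0

    def test_no_observations_rejected(self):
        with pytest.raises(ValueError):
            calling.panel_average([], "m")

    def test_noisy_panel_mean_concentrates(self, three_site_marker):
        """Mean of 96 noisy euploid panel members sits within the
        delta-method 3-sigma band of the noise-free cluster position."""
        from clustershift.types import SimConfig

        cfg = SimConfig(n_markers=12, seed=77, n_panel=96, noise_sd=0.05)
        res = sim.simulate_experiment(cfg)
        panel_ids = res.truth["panel_ids"]
        noise_free = sim.simulate_experiment(
            SimConfig(n_markers=12, seed=77, n_panel=1, noise_sd=0.0)
        )
        truth_theta = noise_free.intensities.set_index(["sample_id", "marker_name"])
        for m in res.markers:
            rows = res.intensities[
                (res.intensities.marker_name == m.name)
                & (res.intensities.sample_id.isin(panel_ids))
            ]
            av = calling.panel_average(
                [
                    IntensityObservation(r.sample_id, r.marker_name, r.norm_theta, r.norm_r)
                    for r in rows.itertuples(index=False)
                ],
                m.name,
            )
            t0 = truth_theta.loc[("Chara", m.name), "norm_theta"]
            x = sum(2 * s.gain for s in m.sites if s.allele == "A")
            y = sum(2 * s.gain for s in m.sites if s.allele == "B")
            if x == 0 or y == 0:
                continue  # boundary clusters clamp; handled by flag margins
            sigma_theta = TWO_OVER_PI * 0.05 / math.hypot(x, y)
            assert abs(av.norm_theta - t0) <= 3.5 * sigma_theta / math.sqrt(96)


class TestFlagMarker:
    cfg = CallerConfig()

    def shift(self, d_theta, d_r, ref="parent"):
        return ClusterShift("m", ref, d_theta, d_r)

    def test_theta_axis(self):
        assert calling.flag_marker(self.shift(-0.295167, 0.0), None, self.cfg)

    def test_nothing_shifts_nothing_flags(self):
        assert not calling.flag_marker(self.shift(0.0, 0.0), None, self.cfg)

    def test_r_axis_rescues_subthreshold_theta(self):
        assert calling.flag_marker(self.shift(0.09, 0.6), None, self.cfg)

    def test_tie_at_threshold_flags(self):
        assert calling.flag_marker(self.shift(0.1, 0.0), None, self.cfg)
        assert calling.flag_marker(self.shift(0.0, 0.5), None, self.cfg)

    def test_panel_concordance_required(self):
        flagged = calling.flag_marker(
            self.shift(0.3, 0.0), self.shift(0.0, 0.0, "panel_average"), self.cfg
        )
        assert not flagged
        relaxed = CallerConfig(require_panel_concordance=False)
        assert calling.flag_marker(
            self.shift(0.3, 0.0), self.shift(0.0, 0.0, "panel_average"), relaxed
        )

    def test_undefined_theta_falls_back_to_r(self):
        assert calling.flag_marker(self.shift(math.nan, 2.0), None, self.cfg)
        assert not calling.flag_marker(self.shift(math.nan, 0.2), None, self.cfg)


class TestNullAndHet:
    def test_null_floor(self):
        assert calling.detect_null(obs("m", math.nan, 0.0), 0.2)
        assert calling.detect_null(obs("m", 0.4, 0.19), 0.2)
        assert not calling.detect_null(obs("m", 1.0, 4.0), 0.2)

    def test_het_confirmed_at_closed_form_midpoint(self):
        """F1 cluster of the 3-site probe: midpoint gap is 0.0084."""
        got = calling.confirm_het(
            obs("p", THETA_EUPLOID, 6.0), obs("m", 1.0, 4.0), obs("f1", THETA_HET, 5.0),
            het_tolerance=0.05,
        )
        assert got is True
        gap = abs(THETA_HET - (THETA_EUPLOID + 1.0) / 2.0)
        assert gap == pytest.approx(0.008375, abs=1e-6)

    def test_f1_equal_to_parent_not_confirmed(self):
        assert calling.confirm_het(
            obs("p", 0.5, 4.0), obs("m", 1.0, 2.0), obs("f1", 0.5, 3.0), 0.05
        ) is False

    def test_f1_outside_span_not_confirmed(self):
        assert calling.confirm_het(
            obs("p", 0.5, 4.0), obs("m", 1.0, 2.0), obs("f1", 0.3, 3.0), 0.05
        ) is False

    def test_undefined_theta_indeterminate(self):
        assert calling.confirm_het(
            obs("p", 0.5, 4.0), obs("m", math.nan, 0.0), obs("f1", 0.7, 3.0), 0.05
        ) is None

    def test_midpoint_tolerance_enforced(self):
        assert calling.confirm_het(
            obs("p", 0.0, 4.0), obs("m", 1.0, 2.0), obs("f1", 0.9, 3.0), 0.05
        ) is False


def _single_site_call(name, sub, status):
    shift = ClusterShift(name, "parent", 0.5, 2.0)
    return DeletionCall(name, status, True, None, sub, shift)


def _marker(name, sub, pos, n_sites=1):
    sites = [HybridisationSite(sub, pos, "A")]
    others = [s for s in ("6A", "6B", "6D") if s != sub]
    for extra in others[: n_sites - 1]:
        sites.append(HybridisationSite(extra, pos, "B"))
    return MarkerRecord(1, name, sub, pos, pos + 100, tuple(sites))


class TestAssignSubgenome:
    def test_single_null_names_subgenome(self):
        calls = [_single_site_call("a", "6A", "null")]
        label, conflicts = calling.assign_subgenome(calls, [_marker("a", "6A", 100)])
        assert label == "6A" and not conflicts

    def test_no_single_site_nulls_unassigned(self):
        calls = [_single_site_call("a", None, "poly")]
        label, conflicts = calling.assign_subgenome(
            calls, [_marker("a", "6A", 100, n_sites=3)]
        )
        assert label is None and not conflicts

    def test_conflicting_nulls_reported(self):
        calls = [
            _single_site_call("a", "6A", "null"),
            _single_site_call("b", "6B", "null"),
        ]
        markers = [_marker("a", "6A", 100), _marker("b", "6B", 100)]
        label, conflicts = calling.assign_subgenome(calls, markers)
        assert label is None and conflicts == ["6A", "6B"]

    def test_end_to_end_recovery_on_simulated_6b_deletion(self):
        from clustershift.types import SimConfig, TrueDeletion

        cfg = SimConfig(
            n_markers=120, seed=31, n_panel=4, noise_sd=0.0,
            multi_site_fraction=0.5,
            deletions={"mut": [TrueDeletion("6B", 20_000_000, 60_000_000)]},
        )
        res = sim.simulate_experiment(cfg)
        calls, _ = calling.call_sample(
            res.intensities, res.markers, parent_id="Chara", sample_id="mut",
            panel_ids=res.truth["panel_ids"],
        )
        from clustershift import mapping

        intervals = mapping.map_intervals(calls, res.markers)
        hit = [iv for iv in intervals if iv.chromosome == "6B"]
        assert hit and hit[0].subgenome == "6B"


class TestBiotypeExclusion:
    def test_identical_stocks_exclude_nothing(self):
        calls = [_single_site_call("a", "6A", "poly")]
        stock = [obs("hib", 0.2, 2.0, "a")]
        same = [obs("bc", 0.2, 2.0, "a")]
        kept, report = calling.exclude_biotype_markers(calls, stock, same, 0.1)
        assert report == [] and not kept[0].excluded_biotype

    def test_allele_swap_excluded_and_demoted(self):
        calls = [_single_site_call("a", "6A", "poly")]
        kept, report = calling.exclude_biotype_markers(
            calls, [obs("hib", 0.0, 2.0, "a")], [obs("bc", 1.0, 2.0, "a")], 0.1
        )
        assert report == ["a"]
        assert kept[0].excluded_biotype and kept[0].status == "none"

    def test_null_discordance_caught_via_r(self):
        calls = [_single_site_call("a", "6A", "poly")]
        kept, report = calling.exclude_biotype_markers(
            calls, [obs("hib", 0.5, 2.0, "a")], [obs("bc", math.nan, 0.0, "a")],
            0.1, r_threshold=0.5,
        )
        assert report == ["a"]


class TestOracleEquivalence:
    def test_noise_free_flags_match_brute_force(self, small_deletion_config):
        res = sim.simulate_experiment(small_deletion_config)
        calls, _ = calling.call_sample(
            res.intensities, res.markers, parent_id="Chara", sample_id="mut",
            panel_ids=res.truth["panel_ids"],
        )
        flagged = {c.marker_name for c in calls if c.flagged}
        expected = validation.predicted_flags(
            res.markers, small_deletion_config.deletions["mut"]
        )
        assert flagged == expected

    def test_noisy_betweenness_of_informative_f1_markers(self, noisy_deletion_config):
        """Under channel noise the F1 still sits strictly between parent
        and mutant wherever the theta separation is informative."""
        res = sim.simulate_experiment(noisy_deletion_config)
        calls, _ = calling.call_sample(
            res.intensities, res.markers, parent_id="Chara", sample_id="mut",
            f1_id="mut_f1", panel_ids=res.truth["panel_ids"],
        )
        wide = res.intensities.pivot(index="marker_name", columns="sample_id",
                                     values="norm_theta")
        multi = {m.name for m in res.markers if not m.single_site}
        checked = 0
        for c in calls:
            if not (c.flagged and c.marker_name in multi):
                continue
            tp, tm, tf = wide.loc[c.marker_name, ["Chara", "mut", "mut_f1"]]
            if any(math.isnan(t) for t in (tp, tm, tf)) or abs(tp - tm) < 0.1:
                continue
            checked += 1
            assert min(tp, tm) < tf < max(tp, tm)
        assert checked > 0

    def test_missing_parent_sample_named_in_error(self, small_deletion_config):
        res = sim.simulate_experiment(small_deletion_config)
        with pytest.raises(ValueError, match="nosuch"):
            calling.call_sample(
                res.intensities, res.markers, parent_id="nosuch", sample_id="mut"
            )
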