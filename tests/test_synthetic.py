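"""Synthetic cohort generator: determinism, variance calibration, trajectory
limit cases, and reproduction-schedule structure."""

import numpy as np
import pandas as pd
import pytest

import clonalfish as cf
from clonalfish import lmm
from clonalfish.errors import ValidationError
from clonalfish.trajectory import compute_activity, summarize_day


class TestCohort:
    def test_same_seed_gives_identical_cohorts(self):
        cfg = cf.SimConfig(seed=123)
        a = cf.simulate_cohort(cfg)
        b = cf.simulate_cohort(cfg)
        assert a == b

    def test_datasets_bitwise_reproducible(self):
        cfg = cf.SimConfig(n_individuals=8, horizon_days=120)
        d1 = cf.simulate_dataset(cfg, seed=5)
        d2 = cf.simulate_dataset(cfg, seed=5)
        for k in d1:
            pd.testing.assert_frame_equal(d1[k], d2[k])

    def test_zero_between_variance_collapses_latents(self):
        cfg = cf.SimConfig(V_ID_act=0.0)
        cohort = cf.simulate_cohort(cfg)
        assert all(ind.u_act == 0.0 for ind in cohort)

    def test_latent_variance_calibrated_at_large_n(self):
        """n = 5000, V_ID_act = 1 -> sample variance within 5%."""
        cfg = cf.SimConfig(n_individuals=5000, V_ID_act=1.0)
        cohort = cf.simulate_cohort(cfg, np.random.default_rng(2))
        u = np.array([ind.u_act for ind in cohort])
        assert np.var(u, ddof=1) == pytest.approx(1.0, rel=0.05)

    def test_latent_correlation_calibrated(self):
        cfg = cf.SimConfig(n_individuals=5000, rho_act_feed=-0.5)
        cohort = cf.simulate_cohort(cfg, np.random.default_rng(3))
        ua = np.array([i.u_act for i in cohort])
        uf = np.array([i.u_feed for i in cohort])
        assert np.corrcoef(ua, uf)[0, 1] == pytest.approx(-0.5, abs=0.05)

    def test_mothers_cycle_through_three_levels(self):
        cohort = cf.simulate_cohort(cf.SimConfig())
        assert {i.mother_id for i in cohort} == {"M1", "M2", "M3"}

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"V_ID_act": -0.1}, "V_ID_act"),
            ({"rho_act_feed": 1.5}, "rho_act_feed"),
            ({"step_s": 0.0}, "step_s"),
            ({"zone_w_cm": 50.0}, "zone"),
            ({"gestation_days": 0.0}, "gestation_days"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            cf.SimConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = cf.SimConfig(n_individuals=7, rho_act_feed=-0.3)
        cfg.to_yaml(tmp_path / "sim.yaml")
        assert cf.SimConfig.from_yaml(tmp_path / "sim.yaml") == cfg


class TestTrajectories:
    def test_zero_speed_scale_gives_stationary_track(self, scaled_traj_config):
        from dataclasses import replace

        cfg = replace(scaled_traj_config, base_speed_scale=0.0)
        ind = cf.simulate_cohort(cfg)[0]
        traj = cf.simulate_trajectory(ind, 1, cfg, np.random.default_rng(1))
        act = traj[traj.phase == "activity"]
        assert compute_activity(act, step_s=cfg.step_s) == 0.0

    def test_infinite_attraction_confines_walk_to_zone(self, scaled_traj_config):
        # fine time step so pursuit steps are small relative to the zone
        from dataclasses import replace

        cfg = replace(
            scaled_traj_config, step_s=0.2, feeding_phase_h=0.02,
            activity_phase_h=0.002, V_res_act=0.0,
        )
        ind = cf.LatentIndividual("F1", 0.0, 1e4, 0.0, 0.0, "M1")
        traj = cf.simulate_trajectory(ind, 1, cfg, np.random.default_rng(2))
        feed = traj[traj.phase == "feeding"]
        inside = cfg.zone.contains(
            feed["x_cm"].to_numpy(), feed["y_cm"].to_numpy()
        )
        assert inside.mean() > 0.9  # after an initial approach transient

    def test_walk_stays_inside_arena(self, scaled_traj_config):
        cfg = scaled_traj_config
        ind = cf.simulate_cohort(cfg)[1]
        traj = cf.simulate_trajectory(ind, 2, cfg, np.random.default_rng(3))
        assert traj["x_cm"].between(0, cfg.arena_w_cm).all()
        assert traj["y_cm"].between(0, cfg.arena_h_cm).all()

    def test_day_out_of_range_rejected(self, scaled_traj_config):
        ind = cf.simulate_cohort(scaled_traj_config)[0]
        with pytest.raises(ValidationError):
            cf.simulate_trajectory(
                ind, 99, scaled_traj_config, np.random.default_rng(0)
            )

    def test_metrics_from_tracks_recover_high_repeatability(self):
        """V_ID_act = 1, tiny V_res: log-activity repeatability near 1."""
        cfg = cf.SimConfig(
            n_individuals=10,
            n_days_behavior=5,
            step_s=1.0,
            activity_phase_h=0.1,
            feeding_phase_h=0.02,
            V_ID_act=1.0,
            V_res_act=0.001,
            act_age_slope=0.0,
        )
        rng = np.random.default_rng(11)
        cohort = cf.simulate_cohort(cfg, rng)
        rows = []
        for ind in cohort:
            for day in range(1, cfg.n_days_behavior + 1):
                traj = cf.simulate_trajectory(ind, day, cfg, rng)
                rows.append(summarize_day(traj, cfg.zone, step_s=cfg.step_s))
        behavior = pd.DataFrame(rows)
        fit = lmm.fit_lmm(
            behavior,
            lmm.ModelSpec("activity_cm_per_s", (), "individual_id",
                          log_response=True),
        )
        assert lmm.repeatability(fit) > 0.9


class TestGrowthGenerator:
    def test_zero_noise_lies_exactly_on_curve(self):
        cfg = cf.SimConfig(size_noise_cm=0.0, horizon_days=140)
        ind = cf.simulate_cohort(cfg)[0]
        records, params = cf.simulate_growth(ind, 30.0, cfg, np.random.default_rng(4))
        expected = cf.vb_length(records["age_days"].to_numpy(), params)
        np.testing.assert_allclose(records["length_cm"].to_numpy(), expected)

    def test_negative_linf_configuration_rejected(self):
        cfg = cf.SimConfig(vb_Linf_base=0.01, beta_feed_Linf=0.02, linf_sd=0.0)
        ind = cf.simulate_cohort(cfg)[0]
        with pytest.raises(ValidationError, match="L_inf"):
            cf.simulate_growth(ind, -10.0, cfg, np.random.default_rng(0))

    def test_null_feeding_effect_gives_flat_feeding_linf_slope(self):
        """beta_feed_Linf = 0: regression of true L_inf on feeding is null."""
        cfg = cf.SimConfig(n_individuals=300, beta_feed_Linf=0.0)
        data = cf.simulate_dataset(cfg, seed=6)
        mf = data["behavior"].groupby("individual_id")["feeding_min"].mean()
        df = data["truth"].assign(mean_feeding=data["truth"]["individual_id"].map(mf))
        slope = np.polyfit(df["mean_feeding"], df["L_inf_true"], 1)[0]
        assert abs(slope) < 0.005  # cm per minute, truth is 0


class TestReproductionGenerator:
    def test_onset_beyond_horizon_gives_no_broods(self):
        cfg = cf.SimConfig(
            onset_base_days=500.0, onset_sd_days=0.0, onset_min_days=400.0
        )
        ind = cf.simulate_cohort(cfg)[0]
        params = cf.VBParams(cfg.expected_linf, 0.02, -4.0)
        broods, offspring = cf.simulate_reproduction(
            ind, params, cfg, np.random.default_rng(1)
        )
        assert broods.empty and offspring.empty

    def test_brood_spacing_matches_gestation(self):
        data = cf.simulate_dataset(cf.SimConfig(), seed=9)
        gaps = data["broods"].groupby("individual_id")[
            "age_at_parturition_days"
        ].apply(lambda s: s.sort_values().diff().dropna())
        assert (gaps >= 30.0 - 3.0 - 1e-9).all()
        assert (gaps <= 30.0 + 3.0 + 1e-9).all()

    def test_mean_broods_per_female_near_study_value(self):
        """Defaults are tuned to ~4.5 broods per female over 280 days."""
        means = []
        for seed in range(6):
            data = cf.simulate_dataset(cf.SimConfig(), seed=seed)
            means.append(
                data["broods"].groupby("individual_id").size().mean()
            )
        assert np.mean(means) == pytest.approx(4.5, abs=0.35)

    def test_offspring_rows_match_brood_sizes(self):
        data = cf.simulate_dataset(cf.SimConfig(n_individuals=10), seed=3)
        counts = data["offspring"].groupby("brood_id").size()
        sizes = data["broods"].set_index("brood_id")["brood_size"]
        measured = sizes[counts.index]
        assert (counts == measured).all()

    def test_unmeasured_broods_have_no_offspring_rows(self):
        cfg = cf.SimConfig(n_individuals=20, p_brood_unmeasured=0.3)
        data = cf.simulate_dataset(cfg, seed=8)
        measured_ids = set(data["offspring"]["brood_id"])
        all_ids = set(data["broods"]["brood_id"])
        assert measured_ids < all_ids
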