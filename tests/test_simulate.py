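import numpy as np
import pandas as pd
import pytest

from baystdetect import (
    SimulationConfig,
    SpaceTimePanel,
    build_spatial_graph,
    build_temporal_graph,
    covariates,
    generate_panel,
    grid_graph,
    icar_structure,
    inject_unusual,
    make_common_surface,
    random_planar_graph,
    sample_icar,
    simulate_dataset,
    synth_population,
)
from baystdetect.simulate import SimulationError, deviation_trend, substream


class TestSampleIcar:
    def test_component_sums_vanish(self):
        g = build_spatial_graph([("A", "B"), ("C", "D")], ["A", "B", "C", "D", "E"])
        s = icar_structure(g)
        x = sample_icar(s, 0.8, np.random.default_rng(0))
        assert abs(x[0] + x[1]) < 1e-8
        assert abs(x[2] + x[3]) < 1e-8
        assert x[4] == pytest.approx(0.0, abs=1e-12)  # isolated area pinned

    def test_pairwise_difference_variance_closed_form(self):
        # path of 2: R has single eigenvalue 2, x = c*(1,-1)/sqrt(2) with
        # c ~ N(0, sigma^2/2), so var(x2 - x1) = sigma^2
        s = icar_structure(build_temporal_graph(2))
        rng = np.random.default_rng(3)
        sigma = 0.7
        diffs = np.array([np.diff(sample_icar(s, sigma, rng))[0] for _ in range(20000)])
        assert diffs.var() == pytest.approx(sigma**2, rel=0.05)

    def test_small_sigma_limit(self, path3_structure):
        x = sample_icar(path3_structure, 1e-9, np.random.default_rng(1))
        assert np.all(np.abs(x) < 1e-7)

    def test_nonpositive_sigma_rejected(self, path3_structure):
        with pytest.raises(SimulationError):
            sample_icar(path3_structure, 0.0, np.random.default_rng(0))


class TestCommonSurface:
    def _structures(self, cfg):
        g = grid_graph(3, 3)
        return icar_structure(g), icar_structure(build_temporal_graph(cfg.n_times))

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(grid=(3, 3), n_areas=9, n_times=6)
        sp, tp = self._structures(cfg)
        t1 = make_common_surface(cfg, sp, tp, np.random.default_rng(7))
        t2 = make_common_surface(cfg, sp, tp, np.random.default_rng(7))
        assert np.array_equal(t1.h, t2.h)
        assert np.array_equal(t1.gamma, t2.gamma)

    def test_h_minus_v_variance_matches_sigma_h(self):
        cfg = SimulationConfig(grid=(3, 3), n_areas=9, n_times=4, sigma_h=0.25)
        sp, tp = self._structures(cfg)
        rng = np.random.default_rng(11)
        resid = np.concatenate(
            [(lambda t: t.h - t.v)(make_common_surface(cfg, sp, tp, rng)) for _ in range(1200)]
        )
        assert resid.var() == pytest.approx(cfg.sigma_h**2, rel=0.1)

    def test_gamma_centred_and_peaks_mid_series(self):
        cfg = SimulationConfig(grid=(3, 3), n_areas=9, n_times=8,
                               sigma_gamma=0.01, seasonal_amplitude=0.5)
        sp, tp = self._structures(cfg)
        t = make_common_surface(cfg, sp, tp, np.random.default_rng(2))
        assert t.gamma.mean() == pytest.approx(0.0, abs=1e-10)
        assert int(np.argmax(t.gamma)) == cfg.peak_time


class TestInjectUnusual:
    @pytest.fixture()
    def base_truth(self):
        cfg = SimulationConfig(grid=(3, 3), n_areas=9, n_times=8)
        g = grid_graph(3, 3)
        return make_common_surface(
            cfg, icar_structure(g), icar_structure(build_temporal_graph(8)),
            np.random.default_rng(4),
        )

    def test_flat_injection_zeroes_trend(self, base_truth):
        t = inject_unusual(base_truth, [2], shape="flat")
        assert np.allclose(t.K_unusual[2], 0.0)
        assert t.z[2] == 0 and t.z.sum() == 8

    def test_spike_offset_arithmetic(self, base_truth):
        m, st = 0.9, 3
        t = inject_unusual(base_truth, [1], shape="spike", magnitude=m, spike_time=st)
        k = t.K_unusual[1]
        # spike adds m at t*, then recentring subtracts m/T everywhere
        expect = base_truth.gamma.copy()
        expect[st] += m
        expect -= expect.mean()
        assert np.allclose(k, expect)

    def test_no_injection_leaves_truth_unchanged(self, base_truth):
        t = inject_unusual(base_truth, [])
        assert np.array_equal(t.z, np.ones(9))
        assert not t.K_unusual

    def test_zero_magnitude_warns_for_detectable_shapes(self, base_truth):
        with pytest.warns(UserWarning, match="undetectable"):
            inject_unusual(base_truth, [0], shape="spike", magnitude=0.0)

    def test_all_shapes_recentred(self, base_truth):
        for shape in ("flat", "shifted_peak", "ramp", "spike"):
            k = deviation_trend(base_truth.gamma, shape, 0.7, spike_time=2)
            assert k.mean() == pytest.approx(0.0, abs=1e-12)

    def test_invalid_ids_rejected(self, base_truth):
        with pytest.raises(SimulationError):
            inject_unusual(base_truth, [99])
        with pytest.raises(SimulationError):
            inject_unusual(base_truth, [1, 1])


class TestGeneratePanel:
    def test_law_of_large_numbers_at_unit_risk(self):
        # mu = 1 everywhere, E = 1e4 over 1000 areas: mean y/E ~ 1
        from baystdetect.simulate import GroundTruth

        n = 1000
        truth = GroundTruth(
            alpha0=0.0, h=np.zeros(n), v=np.zeros(n), gamma=np.zeros(4),
            K_unusual={}, z=np.ones(n, dtype=np.int8), beta=np.array([]),
            area_labels=tuple(f"a{i}" for i in range(n)),
        )
        panel = generate_panel(truth, np.full(n, 1e4), np.random.default_rng(0))
        assert (panel.y / panel.E[:, None]).mean() == pytest.approx(1.0, abs=5e-3)

    def test_fixed_seed_identical_panels(self):
        cfg = SimulationConfig(grid=(3, 3), n_areas=9, n_times=5, seed=5)
        p1, t1, _ = simulate_dataset(cfg)
        p2, t2, _ = simulate_dataset(cfg)
        assert np.array_equal(p1.y, p2.y)
        assert np.array_equal(t1.gamma, t2.gamma)

    def test_counts_conditionally_poisson(self):
        # index of dispersion of replicated y at fixed mu, E within 3 SE of 1
        from baystdetect.simulate import GroundTruth

        truth = GroundTruth(
            alpha0=0.2, h=np.array([0.1]), v=np.array([0.0]),
            gamma=np.array([0.3, -0.3]), K_unusual={},
            z=np.ones(1, dtype=np.int8), beta=np.array([]), area_labels=("a",),
        )
        rng = np.random.default_rng(8)
        reps = np.array(
            [generate_panel(truth, np.array([50.0]), rng).y[0, 0] for _ in range(4000)]
        )
        disp = reps.var() / reps.mean()
        se = np.sqrt(2.0 / len(reps))  # var of dispersion index under Poisson
        assert abs(disp - 1.0) < 3 * se

    def test_panel_passes_model_validators(self):
        cfg = SimulationConfig(grid=(4, 4), n_areas=16, n_times=6, seed=1)
        panel, _, _ = simulate_dataset(cfg)
        rebuilt = SpaceTimePanel.from_long(panel.to_long())
        assert np.array_equal(rebuilt.y, panel.y)
        assert np.allclose(rebuilt.E, panel.E)

    def test_extreme_rate_clipped_with_warning(self):
        from baystdetect.simulate import GroundTruth

        truth = GroundTruth(
            alpha0=25.0, h=np.zeros(1), v=np.zeros(1), gamma=np.zeros(2),
            K_unusual={}, z=np.ones(1, dtype=np.int8), beta=np.array([]),
            area_labels=("a",),
        )
        with pytest.warns(UserWarning, match="clipping"):
            generate_panel(truth, np.array([1.0]), np.random.default_rng(0))


class TestSynthPopulation:
    def test_totals_and_balanced_sex_ratio(self):
        cfg = SimulationConfig(grid=(3, 3), n_areas=9, persons_per_area=20000)
        pop = synth_population(cfg, substream(0, "population"))
        total = pop["count"].sum()
        assert total == pytest.approx(9 * 20000, rel=0.25)
        cov = covariates(pop, {b for b in pop["age_band"].unique() if b != "85+"})
        assert np.all((cov["mf_ratio"] > 0.6) & (cov["mf_ratio"] < 1.6))
        assert cov["mf_ratio"].mean() == pytest.approx(1.0, abs=0.06)

    def test_covariates_vary_between_areas(self):
        from baystdetect.simulate import ACTIVE_BANDS

        cfg = SimulationConfig(grid=(4, 4), n_areas=16)
        pop = synth_population(cfg, substream(3, "population"))
        cov = covariates(pop, set(ACTIVE_BANDS))
        assert cov["pct_active"].std() > 0.2
        assert (cov["pct_active"] <= 100).all() and (cov["pct_active"] > 0).all()


class TestConfigYaml:
    def test_shipped_default_config_loads(self):
        import baystdetect.simulate as sim
        from pathlib import Path

        path = Path(sim.__file__).parent / "default_simulation.yaml"
        cfg = sim.load_simulation_config(path)
        assert cfg == SimulationConfig()

    def test_roundtrip(self, tmp_path):
        from baystdetect import dump_simulation_config, load_simulation_config

        cfg = SimulationConfig(grid=(4, 5), frac_unusual=0.1,
                               deviation_shape="spike", seed=3)
        f = tmp_path / "sim.yaml"
        dump_simulation_config(cfg, f)
        assert load_simulation_config(f) == cfg

    def test_truth_json_export(self, tmp_path):
        import json

        cfg = SimulationConfig(grid=(3, 3), n_areas=9, n_times=4,
                               frac_unusual=0.2, seed=8)
        _, truth, _ = simulate_dataset(cfg)
        f = tmp_path / "truth.json"
        truth.to_json(f)
        back = json.loads(f.read_text())
        assert back["z"] == truth.z.tolist()
        assert np.allclose(back["gamma"], truth.gamma)
        assert set(back["K_unusual"]) == {str(i) for i in truth.unusual_indices}


class TestGraphGenerators:
    def test_planar_graph_connected_and_loop_free(self):
        g = random_planar_graph(40, np.random.default_rng(2))
        assert g.connected
        assert all(i != j for i, j in g.edges)

    def test_null_config_all_usual(self):
        cfg = SimulationConfig(grid=(3, 3), n_areas=9, frac_unusual=0.0, seed=2)
        _, truth, _ = simulate_dataset(cfg)
        assert truth.z.all()

    def test_fraction_injected_matches_config(self):
        cfg = SimulationConfig(
            grid=(5, 5), n_areas=25, frac_unusual=0.2, seed=2,
            deviation_shape="ramp",
        )
        _, truth, _ = simulate_dataset(cfg)
        assert len(truth.unusual_indices) == 5
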