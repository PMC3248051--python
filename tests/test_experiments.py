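"""Synthetic-study generation: schemes, noise families, fixtures."""

import numpy as np
import pytest

import thermokin as tk
from thermokin.model_io import write_measurements


class TestSamplingTimes:
    def test_uniform_spacing(self):
        tq, ts = tk.sampling_times(tk.SamplingScheme(kind="uniform", Q=4, t_max=1.0))
        assert np.allclose(tq, [0.2, 0.4, 0.6, 0.8])
        assert ts == 1.0

    def test_logarithmic_geometric_spacing(self):
        sch = tk.SamplingScheme(kind="logarithmic", Q=3, t_max=1.0, t_min=0.01)
        tq, ts = tk.sampling_times(sch)
        assert np.allclose(tq, [0.01, np.sqrt(0.01 * 0.75), 0.75], rtol=1e-12)
        assert ts == 1.0

    def test_q2_logarithmic_endpoints_only(self):
        tq, _ = tk.sampling_times(tk.SamplingScheme(kind="logarithmic", Q=2, t_max=3.0))
        assert np.allclose(tq, [0.03, 2.0])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            tk.SamplingScheme(kind="logarithmic", Q=3, t_max=1.0, t_min=2.0)
        with pytest.raises(ValueError):
            tk.SamplingScheme(kind="uniform", Q=1, t_max=1.0)


class TestNoiseModels:
    def test_zero_sigma_reproduces_log_trajectory(self, two_state):
        net, _, ktrue, design = two_state
        sch = tk.SamplingScheme(Q=4, t_max=design.t_max)
        data = tk.generate_measurements(net, ktrue, design, tk.NoiseModel(sigma=0.0), 0, scheme=sch)
        traj = tk.simulate(
            net, ktrue, data.design, 0,
            eval_times=np.append(data.transient_times, data.steady_time),
        )
        assert np.allclose(data.transient[:, 0, :], np.log(traj.concentrations[:-1]).T, atol=1e-9)
        assert np.allclose(data.steady[:, 0], np.log(traj.concentrations[-1]), atol=1e-9)

    def test_uniform_family_support_and_sd(self):
        noise = tk.NoiseModel(family="iid_uniform", sigma=0.3)
        rng = np.random.default_rng(0)
        draws = noise.draw_series(np.arange(100_000, dtype=float), rng)
        assert np.max(np.abs(draws)) <= np.sqrt(3) * 0.3 + 1e-12
        assert draws.std() == pytest.approx(0.3, rel=0.01)

    def test_correlated_family_lag_one_correlation(self):
        noise = tk.NoiseModel(family="correlated_gaussian", sigma=0.5)
        rng = np.random.default_rng(1)
        t = np.array([0.0, 1.0])
        pairs = np.array([noise.draw_series(t, rng) for _ in range(10_000)])
        corr = np.corrcoef(pairs.T)[0, 1]
        se = 1.0 / np.sqrt(10_000)
        assert corr == pytest.approx(np.exp(-1.0), abs=3 * se + 0.01)

    def test_residual_variance_matches_likelihood_assumption(self, two_state, var_hyper, toy_hyper):
        # phi(kappa_true)/[N(P+1)Q] -> sigma^2 + 2b/[N(P+1)Q] under iid Gaussian noise
        net, _, ktrue, design = two_state
        sigma = 0.3
        sch = tk.SamplingScheme(Q=6, t_max=design.t_max)
        pooled = []
        for seed in range(40):
            data = tk.generate_measurements(
                net, ktrue, design, tk.NoiseModel(sigma=sigma), seed, scheme=sch
            )
            ctx = tk.build_context(net, data.design, data, var_hyper, toy_hyper)
            n_obs = net.n_species * 1 * 6
            pooled.append((tk.phi(ktrue, ctx) - 2.0) / n_obs)
        assert np.mean(pooled) == pytest.approx(sigma**2, rel=0.15)

    def test_infeasible_truth_refused(self, triangle):
        net, kpub, _, design = triangle  # published set violates the loop condition
        sch = tk.SamplingScheme(Q=3, t_max=design.t_max)
        with pytest.raises(ValueError, match="Wegscheider"):
            tk.generate_measurements(net, kpub, design, tk.NoiseModel(sigma=0.1), 0, scheme=sch)
        tk.generate_measurements(
            net, kpub, design, tk.NoiseModel(sigma=0.1), 0, scheme=sch, allow_infeasible=True
        )


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_csv(self, chain3, tmp_path):
        net, _, ktrue, design = chain3
        sch = tk.SamplingScheme(Q=4, t_max=design.t_max)
        payloads = []
        for run in range(2):
            data = tk.generate_measurements(
                net, ktrue, design, tk.NoiseModel(sigma=0.2), 77, scheme=sch
            )
            path = tmp_path / f"run{run}.csv"
            write_measurements(data, path, net)
            payloads.append(path.read_bytes())
        assert payloads[0] == payloads[1]

    def test_transient_and_steady_streams_independent(self, two_state):
        # changing Q must not change the steady-state error draw
        net, _, ktrue, design = two_state
        d4 = tk.generate_measurements(
            net, ktrue, design, tk.NoiseModel(sigma=0.4), 5,
            scheme=tk.SamplingScheme(Q=4, t_max=design.t_max),
        )
        d6 = tk.generate_measurements(
            net, ktrue, design, tk.NoiseModel(sigma=0.4), 5,
            scheme=tk.SamplingScheme(Q=6, t_max=design.t_max),
        )
        assert np.allclose(d4.steady, d6.steady)


class TestFixtures:
    def test_two_state_shape(self, two_state):
        net, kpub, ktrue, design = two_state
        assert net.n_species == 2 and net.n_reactions == 1
        assert np.array_equal(kpub.kappa, ktrue.kappa)  # no constraints to project

    def test_triangle_projection_built_in(self, triangle):
        net, kpub, ktrue, _ = triangle
        decomp = tk.decompose(net)
        assert float(np.sum(kpub.z)) == pytest.approx(0.3)
        assert np.allclose(ktrue.kappa, 0.05)
        assert np.max(np.abs(tk.wegscheider_residuals(ktrue, decomp))) < 1e-12

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            tk.fixture_network("pentagon")

    def test_egf_erk_slot_reports_missing_transcription(self):
        with pytest.raises(tk.FixtureUnavailableError, match="transcri"):
            tk.fixture_network("egf_erk_subset")


class TestNoiseRobustness:
    def test_correlated_errors_degrade_but_do_not_break_calibration(
        self, two_state, var_hyper, toy_hyper
    ):
        # correlated errors violate the likelihood's independence assumption:
        # median dynamics error grows on average, yet stays finite and small
        net, _, ktrue, design = two_state
        sch = tk.SamplingScheme(kind="logarithmic", Q=6, t_max=design.t_max)
        meds = {}
        for fam_idx, fam in enumerate(("iid_gaussian", "correlated_gaussian")):
            vals = []
            for seed in range(10):
                ss = np.random.SeedSequence([seed, fam_idx, 2024])
                s1, s2 = ss.spawn(2)
                data = tk.generate_measurements(
                    net, ktrue, design, tk.NoiseModel(family=fam, sigma=0.3),
                    s1, scheme=sch,
                )
                ctx = tk.build_context(net, data.design, data, var_hyper, toy_hyper)
                res = tk.mem_estimate(
                    ctx, tk.SPSAConfig(iterations=100),
                    tk.MCMCConfig(iterations=800), seed=s2,
                )
                med, _ = tk.median_max_abs_error(
                    net, ktrue, tk.KineticParameters(res.kappa_hat), data.design
                )
                vals.append(med)
            meds[fam] = float(np.mean(vals))
        assert meds["correlated_gaussian"] > meds["iid_gaussian"]
        assert meds["correlated_gaussian"] < 0.5  # degraded, not broken


class TestRunDesign:
    def test_replication_and_table_ordering(self, two_state, var_hyper, toy_hyper):
        net, _, ktrue, design = two_state
        base = tk.ExperimentDesign(design.initial_concentrations, {}, t_max=design.t_max)
        rep = tk.ExperimentDesign(
            design.initial_concentrations, {1: 0.0, 2: 0.0}, t_max=design.t_max
        )
        sch = tk.SamplingScheme(Q=3, t_max=design.t_max)
        table, reports = tk.run_design(
            net, ktrue, {"single": base, "x3-replication": rep}, sch,
            tk.NoiseModel(sigma=0.3), var_hyper, toy_hyper,
            tk.SPSAConfig(iterations=40), tk.MCMCConfig(iterations=300),
            seed=3, compute_dynamics_error=False,
        )
        assert set(table["design"]) == {"single", "x3-replication"}
        assert table["D"].is_monotonic_increasing
        assert reports["x3-replication"].rmse.shape == (2,)
        # pi = 0 replication triples the data volume
        assert int(table.set_index("design").loc["x3-replication", "P"]) == 2
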