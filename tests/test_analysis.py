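"""Fluxes, control coefficients, correlations and the covariance experiment."""

import numpy as np
import pandas as pd
import pytest

from eportraffic.analysis import (
    ParameterEnsembleStats,
    control_coefficients,
    correlation_analysis,
    covariance_experiment,
    data_level_correlations,
    fluxes,
    pearson_with_pvalue,
)
from eportraffic.model import StimulusProtocol, simulate
from eportraffic.synth import GeneratorConfig, SAMPLED_PARAMS, generate_dataset


class TestFluxes:
    def test_prestimulus_stationarity(self, acd, median_params):
        """At the ligand-free steady state, exchange fluxes balance and
        degradation equals synthesis."""
        protocol = StimulusProtocol("epo", (0.0, 50.0, 100.0), epo_conc=0.0)
        traj = simulate(acd, median_params, protocol)
        fs = fluxes(acd, median_params, traj, protocol)
        row = fs.at(100.0)
        assert row["F_ItoM"] == pytest.approx(row["F_MtoI"], rel=1e-9)
        assert row["F_deg"] == pytest.approx(median_params.k_syn, rel=1e-9)
        assert row["F_Epo_on"] == 0.0

    def test_empty_endosome_has_no_exit_fluxes(self, acd, median_params):
        protocol = StimulusProtocol("epo", (0.0, 1.0), epo_conc=4.2)
        traj = simulate(acd, median_params, protocol)
        fs = fluxes(acd, median_params, traj, protocol)
        at0 = fs.at(0.0)
        assert at0["F_EpoRstar_REtoM"] == 0.0
        assert at0["F_EpoRstar_deg_REtoEx"] == 0.0

    def test_recycling_flux_magnitude_comparable_to_delivery(self, acd, median_params):
        """Near steady state, complex recycling reaches the order of the
        free-receptor delivery flux."""
        protocol = StimulusProtocol(
            "epo", tuple(np.arange(0.0, 301.0, 10.0)), epo_conc=4.2
        )
        traj = simulate(acd, median_params, protocol)
        row = fluxes(acd, median_params, traj, protocol).at(300.0)
        ratio = row["F_EpoRstar_REtoM"] / row["F_ItoM"]
        assert 0.1 < ratio < 10.0


class TestControlCoefficients:
    def test_summation_to_zero_at_steady_state(self, acd, median_params):
        """Scaling all first-order rates and the synthesis rate leaves the
        steady state unchanged, so the coefficients sum to zero."""
        r = control_coefficients(acd, median_params, target="EpoRstar_m", t=None)
        assert abs(sum(r.values())) <= 1e-3
        r2 = control_coefficients(acd, median_params, target="EpoRstar_RE", t=None)
        assert abs(sum(r2.values())) <= 1e-3

    def test_all_magnitudes_below_one_at_default_parameters(self, acd, median_params):
        """No single rate dominates the complex concentrations.

        The synthesis rate is the exception by construction: the system
        is linear with source k_syn, so its coefficient equals one
        exactly; every other coefficient stays strictly below one.
        """
        for target in ("EpoRstar_m", "EpoRstar_RE"):
            r = control_coefficients(acd, median_params, target=target, t=300.0)
            assert r.pop("k_syn") == pytest.approx(1.0, abs=1e-6)
            assert max(abs(v) for v in r.values()) < 1.0

    def test_synthesis_controls_output_proportionally(self, acd, median_params):
        # every species is proportional to k_syn (linear system, b = k_syn e0)
        r = control_coefficients(acd, median_params, target="EpoRstar_m", t=None)
        assert r["k_syn"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_target_raises(self, acd, median_params):
        with pytest.raises(ZeroDivisionError):
            control_coefficients(acd, median_params, target="EpoRstar_m", t=None,
                                 epo=0.0)


class TestCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        rho, p = pearson_with_pvalue(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)
        assert p < 1e-30

    def test_worked_example_rho_08_n_16(self):
        # t = 0.8*sqrt(14)/0.6 = 4.9889, two-sided p at 14 df
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=16)
            y = rng.normal(size=16)
            rho, p = pearson_with_pvalue(x, y)
            from scipy.stats import pearsonr

            ref = pearsonr(x, y)
            assert rho == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_pvalue(np.ones(5), np.arange(5.0))

    def test_matrix_properties(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            np.exp(rng.normal(size=(20, 4))), columns=list("abcd")
        )
        rho, pval = correlation_analysis(df, log=True)
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert ((pval.values >= 0) & (pval.values <= 1)).all()

    def test_generating_transport_correlation_recovered(self):
        """Sampled true parameters reproduce the built-in positive
        correlation among the four transport rates."""
        from eportraffic.synth import sample_cells, TRANSPORT_PARAMS

        cfg = GeneratorConfig(n_epo_cells=200)
        cells = [c for c in sample_cells(cfg, 2) if c.condition == "epo"]
        df = pd.DataFrame([{p: c.params[p] for p in TRANSPORT_PARAMS} for c in cells])
        rho, _ = correlation_analysis(df, log=True)
        off_diag = rho.values[~np.eye(4, dtype=bool)]
        assert (off_diag > 0.7).all()  # generating rho = 0.9, n = 200


class TestEnsembleStats:
    def test_lognormal_summary_closed_form(self):
        stats = ParameterEnsembleStats(["k"], np.array([0.0]), np.array([[1.0]]))
        summary = stats.summary()
        assert summary.loc["k", "cv"] == pytest.approx(np.sqrt(np.e - 1))
        assert summary.loc["k", "mean"] == pytest.approx(np.exp(0.5))

    def test_sample_cv_matches_closed_form(self, rng):
        stats = ParameterEnsembleStats(["k"], np.array([0.0]), np.array([[0.25]]))
        draws = stats.sample(20000, rng)["k"]
        assert draws.std() / draws.mean() == pytest.approx(
            np.sqrt(np.expm1(0.25)), rel=0.05
        )

    def test_reduction_zeroes_cross_covariances_only(self):
        cfg = GeneratorConfig()
        names = list(SAMPLED_PARAMS)
        cov = cfg.log10_covariance() * np.log(10) ** 2
        stats = ParameterEnsembleStats(names, np.zeros(len(names)), cov)
        red = stats.reduced()
        star = [names.index(p) for p in ("k_MtoRE", "k_REtoM", "k_deg_REtoEx",
                                         "k_deg_REtoI")]
        other = [i for i in range(len(names)) if i not in star]
        for i in star:
            for j in other:
                assert red.log_cov[i, j] == 0.0
            for j in star:
                assert red.log_cov[i, j] == pytest.approx(cov[i, j])
        np.testing.assert_allclose(np.diag(red.log_cov), np.diag(cov))

    def test_psd_repair_flagged(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        stats = ParameterEnsembleStats(["a", "b"], np.zeros(2), bad)._ensure_psd()
        assert stats.repaired
        assert np.linalg.eigvalsh(stats.log_cov).min() >= -1e-12


class TestCovarianceExperiment:
    @pytest.fixture(scope="class")
    def default_stats(self):
        cfg = GeneratorConfig()
        names = list(SAMPLED_PARAMS)
        means = np.log(10.0 ** np.array([cfg.log10_means[p] for p in names]))
        cov = cfg.log10_covariance() * np.log(10) ** 2
        return ParameterEnsembleStats(names, means, cov)

    def test_diagonal_covariance_unchanged_by_reduction(self):
        cfg = GeneratorConfig()
        names = list(SAMPLED_PARAMS)
        means = np.array([cfg.log10_means[p] for p in names]) * np.log(10)
        diag = np.diag([0.3] * len(names))
        stats = ParameterEnsembleStats(names, means, diag)
        full = covariance_experiment(stats, "ACD", n_samples=50, seed=9)
        red = covariance_experiment(stats, "ACD", n_samples=50, seed=9, reduced=True)
        assert full["cv_EpoRstar_m"] == pytest.approx(red["cv_EpoRstar_m"])

    def test_removing_covariances_increases_output_cv(self, default_stats):
        full = covariance_experiment(default_stats, "ACD", n_samples=400, seed=2)
        red = covariance_experiment(default_stats, "ACD", n_samples=400, seed=2,
                                    reduced=True)
        assert red["cv_EpoRstar_m"] > full["cv_EpoRstar_m"]
        assert red["cv_EpoRstar_RE"] > full["cv_EpoRstar_RE"]

    def test_deterministic_given_seed(self, default_stats):
        a = covariance_experiment(default_stats, "ACD", n_samples=50, seed=4)
        b = covariance_experiment(default_stats, "ACD", n_samples=50, seed=4)
        assert a == b


class TestDataLevelCorrelations:
    def test_identical_cells_flagged(self):
        sds = {k: 0.0 for k in GeneratorConfig().log10_sds}
        cfg = GeneratorConfig(n_epo_cells=4, log10_sds=sds, correlations=(),
                              sigma_rel=0.0)
        table, _ = generate_dataset(cfg, 1)
        out = data_level_correlations(table)
        assert out["rho"].isna().all()

    def test_scale_invariance(self, small_dataset):
        _, table, _ = small_dataset
        out1 = data_level_correlations(table)
        scaled = table.copy()
        scaled["value_au"] *= 37.0
        out2 = data_level_correlations(scaled)
        pd.testing.assert_frame_equal(out1, out2)

    def test_membrane_vesicle_concentration_correlation_positive(self):
        """Correlated delivery/retrieval rates couple the two receptor pools."""
        cfg = GeneratorConfig(n_epo_cells=16, sigma_rel=0.05)
        table, _ = generate_dataset(cfg, 12)
        out = data_level_correlations(table).set_index("pair")
        assert out.loc["conc_mem0_vs_ves0", "rho"] > 0

    def test_amounts_need_volumes(self, small_dataset):
        _, table, truth = small_dataset
        volumes = {cid: info["volume_pl"] for cid, info in truth["cells"].items()}
        out = data_level_correlations(table, volumes=volumes)
        assert "amount_tot0_vs_epomem_late" in set(out["pair"])

    def test_missing_timepoint_raises(self, small_dataset):
        _, table, _ = small_dataset
        with pytest.raises(ValueError):
            data_level_correlations(table, t_late=123.0)
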