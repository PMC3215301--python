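import numpy as np
import pytest

from episnet import (DegreeDistribution, all_main_effects, all_pair_weights,
                     fit_power_law, fit_truncated_poisson, power_law_ks,
                     threshold_sweep, topology_report, truncated_poisson_pmf)
from episnet.topology import _poisson_sample, fit_power_curve
from _oracles import oracle_loglog_slope
from conftest import TABLE1_N_VERTICES, TABLE1_REAL_PD, random_dataset


@pytest.fixture
def table1_dd():
    return DegreeDistribution.from_probabilities(TABLE1_REAL_PD,
                                                 TABLE1_N_VERTICES)


class TestTruncatedPoissonPmf:
    def test_zero_degree_has_zero_mass(self):
        for lam in (0.1, 0.5, 3.0):
            assert truncated_poisson_pmf(0, lam) == 0.0

    @pytest.mark.parametrize("lam", [0.01, 0.1, 1.0, 10.0])
    def test_normalized_over_positive_degrees(self, lam):
        d = np.arange(0, 200)  # tail mass far below 1e-12 by d=200
        assert truncated_poisson_pmf(d, lam).sum() == pytest.approx(
            1.0, abs=1e-9)

    def test_matches_direct_formula(self):
        lam = 0.366
        direct = lam * np.exp(-lam) / (1 - np.exp(-lam))
        assert truncated_poisson_pmf(1, lam) == pytest.approx(direct,
                                                              abs=1e-12)
        assert truncated_poisson_pmf(1, lam) == pytest.approx(0.8281,
                                                              abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            truncated_poisson_pmf(-1, 0.5)
        with pytest.raises(ValueError):
            truncated_poisson_pmf(1, 0.0)


class TestPowerLawFit:
    @pytest.mark.parametrize("protocol", ["nonlinear_lsq_with_zeros",
                                          "loglog_linear_regression"])
    def test_exact_power_curve_recovered(self, protocol):
        d = np.arange(1, 12)
        p = 0.615 * d ** -2.01
        c, gamma = fit_power_curve(d, p, protocol=protocol)
        assert c == pytest.approx(0.615, abs=1e-6)
        assert gamma == pytest.approx(2.01, abs=1e-6)

    def test_flat_distribution_gives_gamma_near_zero(self):
        c, gamma = fit_power_curve([1, 2, 3], [1 / 3] * 3)
        assert gamma == pytest.approx(0.0, abs=1e-6)

    def test_table1_loglog_matches_ols_oracle(self, table1_dd):
        fit = fit_power_law(table1_dd, protocol="loglog_linear_regression")
        support = table1_dd.support()
        probs = [table1_dd.p(int(d)) for d in support]
        slope, intercept = oracle_loglog_slope(support, probs)
        assert fit.gamma == pytest.approx(-slope, abs=1e-9)
        assert fit.c == pytest.approx(np.exp(intercept), abs=1e-9)
        assert fit.gamma == pytest.approx(2.3, abs=0.05)

    def test_too_few_support_points(self):
        dd = DegreeDistribution(counts={1: 5, 2: 3}, n_vertices=8)
        with pytest.raises(ValueError, match="at least 3"):
            fit_power_law(dd)

    def test_unknown_protocol(self, table1_dd):
        with pytest.raises(ValueError, match="protocol"):
            fit_power_law(table1_dd, protocol="magic")


class TestPowerLawKS:
    def test_exact_match_gives_zero_stat(self):
        # counts proportional to 1/d on full support 1..3: the fitted model
        # reproduces the empirical pmf exactly
        dd = DegreeDistribution(counts={1: 12, 2: 6, 3: 4}, n_vertices=22)
        fit = fit_power_law(dd, protocol="loglog_linear_regression")
        stat, p = power_law_ks(dd, fit, n_boot=200, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p > 0.95

    def test_reproducible_and_in_unit_interval(self, table1_dd):
        fit = fit_power_law(table1_dd)
        s1, p1 = power_law_ks(table1_dd, fit, n_boot=100, seed=7)
        s2, p2 = power_law_ks(table1_dd, fit, n_boot=100, seed=7)
        assert s1 == s2 and p1 == p2
        assert 0 <= p1 <= 1

    def test_distortion_increases_stat(self):
        dd = DegreeDistribution(counts={1: 12, 2: 6, 3: 4}, n_vertices=22)
        fit = fit_power_law(dd, protocol="loglog_linear_regression")
        base_stat, _ = power_law_ks(dd, fit, n_boot=10, seed=0)
        prev = base_stat
        for shift in (2, 4):  # move vertices from degree 1 to degree 3
            distorted = DegreeDistribution(
                counts={1: 12 - shift, 2: 6, 3: 4 + shift}, n_vertices=22)
            stat, _ = power_law_ks(distorted, fit, n_boot=10, seed=0)
            assert stat > prev
            prev = stat

    def test_geometric_degrees_rejected(self):
        rng = np.random.default_rng(0)
        rejected = 0
        n_seeds = 10
        for s in range(n_seeds):
            degs = rng.geometric(0.35, size=500)
            vals, cnts = np.unique(degs, return_counts=True)
            dd = DegreeDistribution(
                counts={int(v): int(c) for v, c in zip(vals, cnts)},
                n_vertices=500)
            fit = fit_power_law(dd)
            _, p = power_law_ks(dd, fit, n_boot=200, seed=s)
            rejected += p <= 0.05
        assert rejected >= int(0.9 * n_seeds)


class TestTruncatedPoissonFit:
    def test_lambda_uses_all_snps_denominator(self, table1_dd):
        fit = fit_truncated_poisson(table1_dd, m_total=1422, n_boot=10,
                                    seed=0)
        assert fit.lam == pytest.approx(2 * 255 / 1422)
        assert fit.lam == pytest.approx(0.3587, abs=1e-4)
        assert fit.k == pytest.approx(1 - np.exp(-fit.lam))

    def test_m_total_smaller_than_vertices_rejected(self, table1_dd):
        with pytest.raises(ValueError, match="m_total"):
            fit_truncated_poisson(table1_dd, m_total=100)

    def test_poisson_degrees_not_rejected(self):
        lam = 0.4
        # m_total consistent with the truncation: of m_total randomly wired
        # vertices a fraction 1 - e^-lambda survives with degree >= 1
        m_total = round(1000 / -np.expm1(-lam))
        ok = 0
        n_seeds = 10
        for s in range(n_seeds):
            sample = _poisson_sample(np.random.default_rng(100 + s), lam,
                                     1000)
            vals, cnts = np.unique(sample, return_counts=True)
            dd = DegreeDistribution(
                counts={int(v): int(c) for v, c in zip(vals, cnts)},
                n_vertices=1000)
            fit = fit_truncated_poisson(dd, m_total=m_total,
                                        n_boot=200, seed=s)
            ok += fit.ks_p > 0.05
        assert ok >= int(0.8 * n_seeds)


class TestTopologyReport:
    def _fitted(self, seed=0, planted=True):
        from episnet import (PlantedModel, SimulationDesign, build_null,
                             generate_dataset, pair_pvalues, xor_parity)
        from episnet.permutation import property_pvalues
        from episnet import threshold_grid

        planted_models = ([PlantedModel((2, 5), xor_parity())]
                          if planted else [])
        design = SimulationDesign(m_snps=25, n_cases=120, n_controls=180,
                                  planted=planted_models, seed=seed)
        ds = generate_dataset(design)
        pw = all_pair_weights(ds)
        mains = all_main_effects(ds)
        grid = threshold_grid(0.03, 0.0, 0.005)
        null = build_null(ds, n_replicates=40, seed=seed + 1,
                          thresholds=grid)
        pw = pair_pvalues(pw, null)
        sweep = threshold_sweep(pw, 0.03, 0.0, 0.005)
        props = property_pvalues(sweep, null)
        return sweep, props, pw, mains, ds.n_snps

    def test_deterministic_and_well_formed(self):
        sweep, props, pw, mains, m = self._fitted()
        rep1 = topology_report(sweep, props, pw, mains, m_total=m,
                               n_boot=20, seed=3)
        rep2 = topology_report(sweep, props, pw, mains, m_total=m,
                               n_boot=20, seed=3)
        assert rep1.equals(rep2)
        assert len(rep1) == sweep.thresholds.size
        assert set(rep1["n_flags"]) <= {0, 1, 2, 3}
        assert (rep1["n_flags"] == rep1[["flag_properties", "flag_dominant",
                                         "flag_scalefree"]].sum(axis=1)).all()

    def test_null_data_raises_no_full_flag_set(self):
        sweep, props, pw, mains, m = self._fitted(seed=11, planted=False)
        rep = topology_report(sweep, props, pw, mains, m_total=m,
                              n_boot=20, seed=4)
        assert (rep["n_flags"] < 3).all()

    def test_works_without_property_pvalues(self):
        sweep, _, pw, mains, m = self._fitted(seed=2)
        rep = topology_report(sweep, None, pw, mains, m_total=m,
                              n_boot=10, seed=0)
        assert not rep["flag_properties"].any()
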