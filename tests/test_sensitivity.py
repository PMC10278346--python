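"""Parameter distributions, one-way DSA and probabilistic SA."""

import warnings

import numpy as np
import pytest

import tkicea as tk
from tkicea.sensitivity import evaluate_spec, pm20, quadrant_counts


@pytest.fixture(scope="module")
def params(spec):
    return tk.table_parameters(spec)


@pytest.fixture(scope="module")
def psa_small(spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return tk.run_psa(spec, n_iter=400, seed=11)


class TestDistributions:
    def test_gamma_cost_moment_matching(self):
        p = tk.ParamSpec("chemo_cost", 27_200.0, 20_400.0, 34_000.0, "gamma")
        assert p.sd == pytest.approx(3_469.39, abs=0.01)
        draws = tk.parameterize_distribution(p)(np.random.default_rng(0), 100_000)
        assert np.mean(draws) == pytest.approx(27_200.0, rel=0.01)
        assert np.std(draws) == pytest.approx(p.sd, rel=0.03)
        assert np.all(draws > 0)

    def test_beta_utility_moment_matching(self):
        p = tk.ParamSpec("utility_pfs", 0.46, 0.43, 0.48, "beta")
        draws = tk.parameterize_distribution(p)(np.random.default_rng(1), 100_000)
        assert abs(np.mean(draws) - 0.46) < 0.005
        assert np.all((draws > 0) & (draws < 1))

    def test_lognormal_dose_moment_matching(self):
        p = tk.ParamSpec("dose_im", 300.0, 260.0, 340.0, "lognormal")
        draws = tk.parameterize_distribution(p)(np.random.default_rng(2), 100_000)
        assert np.mean(draws) == pytest.approx(300.0, rel=0.01)

    def test_degenerate_range_is_point_mass(self):
        p = tk.ParamSpec("x", 5.0, 5.0, 5.0, "gamma")
        sampler = tk.parameterize_distribution(p)
        assert sampler(np.random.default_rng(0)) == 5.0
        assert np.all(sampler(np.random.default_rng(0), 10) == 5.0)

    def test_impossible_beta_falls_back_to_uniform(self):
        # sd too large for a (0,1) mean → implied shapes non-positive
        p = tk.ParamSpec("u", 0.5, 0.0, 4.0, "beta")
        with pytest.warns(UserWarning, match="uniform"):
            sampler = tk.parameterize_distribution(p)
        draws = sampler(np.random.default_rng(3), 1000)
        assert np.all((draws >= 0.0) & (draws <= 4.0))

    def test_all_tabulated_parameters_moment_match(self, params):
        rng = np.random.default_rng(7)
        for p in params:
            draws = tk.parameterize_distribution(p)(rng, 100_000)
            if p.distribution == "uniform":
                target = (p.low + p.high) / 2.0
            else:
                target = p.base
            assert np.mean(draws) == pytest.approx(target, rel=0.01), p.name

    def test_invalid_paramspec_rejected(self):
        with pytest.raises(ValueError):
            tk.ParamSpec("x", 1.0, 2.0, 3.0, "gamma")  # base below low
        with pytest.raises(ValueError):
            tk.ParamSpec("x", 1.0, 0.5, 2.0, "zipf")
        p20 = pm20("y", 10.0, "gamma")
        assert (p20.low, p20.high) == (8.0, 12.0) and not p20.from_ci


class TestOverrides:
    def test_twelve_tabulated_parameters(self, params):
        assert len(params) == 12
        assert {p.distribution for p in params} == {"gamma", "beta", "lognormal", "uniform"}

    def test_dose_scales_tki_cost(self, spec, params):
        mod = tk.apply_overrides(spec, {"dose_imatinib": 600.0}, params)
        assert mod.arm("imatinib").tki_cost_per_cycle == pytest.approx(2 * 145.0)
        assert mod.arm("dasatinib").tki_cost_per_cycle == 376.0

    def test_named_overrides_land_in_place(self, spec, params):
        mod = tk.apply_overrides(
            spec, {"utility_pfs": 0.43, "pd_cost": 50_000.0, "sae_cost_dasatinib": 2_232.0},
            params,
        )
        assert mod.utility_pfs == 0.43
        assert mod.pd_cost_onetime == 50_000.0
        assert mod.arm("dasatinib").sae_cost_per_cycle == 2_232.0

    def test_unknown_name_rejected(self, spec, params):
        with pytest.raises(KeyError):
            tk.apply_overrides(spec, {"bananas": 1.0}, params)


class TestOneWayDSA:
    def test_one_row_per_parameter(self, spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tbl = tk.one_way_dsa(spec)
        assert len(tbl) == 12
        assert {"icer_low", "icer_high", "nmb_spread"} <= set(tbl.columns)

    def test_degenerate_ranges_reproduce_base_icer(self, spec):
        s = spec.replace(allocation_mode="os-hazard")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            results, _ = evaluate_spec(s)
            a, b = (results[n] for n in s.arm_names)
            base_icer = tk.compare(a, b, s.wtp, s.gdp_per_capita).icer
            degenerate = [
                tk.ParamSpec(p.name, p.base, p.base, p.base, p.distribution)
                for p in tk.table_parameters(s)
            ]
            tbl = tk.one_way_dsa(s, degenerate)
        assert np.allclose(tbl["icer_low"], base_icer, rtol=1e-9)
        assert np.allclose(tbl["icer_high"], base_icer, rtol=1e-9)

    def test_comparator_cost_increase_raises_incremental_cost(self, spec, params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = evaluate_spec(tk.apply_overrides(spec, {"tki_cost_dasatinib": 301.0}, params))[0]
            hi = evaluate_spec(tk.apply_overrides(spec, {"tki_cost_dasatinib": 451.0}, params))[0]
        inc = lambda r: r["dasatinib"].total_cost - r["imatinib"].total_cost
        assert inc(hi) > inc(lo)

    def test_zero_discount_inflates_incremental_qalys(self, spec, params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            base = evaluate_spec(spec)[0]
            nodisc = evaluate_spec(tk.apply_overrides(spec, {"discount_rate": 0.0}, params))[0]
        inc_q = lambda r: r["dasatinib"].total_qaly - r["imatinib"].total_qaly
        assert inc_q(nodisc) > inc_q(base)

    def test_pfs_utility_range_keeps_comparator_favorable(self, spec, params):
        """The comparator stays NMB-favorable across the published PFS-utility CI."""
        for u in (0.43, 0.48):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = evaluate_spec(tk.apply_overrides(spec, {"utility_pfs": u}, params))[0]
            cmp_ = tk.compare(res["imatinib"], res["dasatinib"], spec.wtp,
                              spec.gdp_per_capita)
            assert cmp_.nmb_b > cmp_.nmb_a


class TestPSA:
    def test_degenerate_distributions_reproduce_base_case(self, spec, base_results):
        degenerate = [
            tk.ParamSpec(p.name, p.base, p.base, p.base, p.distribution)
            for p in tk.table_parameters(spec)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            psa = tk.run_psa(spec, degenerate, n_iter=5, seed=1)
        for arm in spec.arm_names:
            assert np.allclose(psa.cost[arm], base_results[arm].total_cost, rtol=1e-9)
            assert np.allclose(psa.qaly[arm], base_results[arm].total_qaly, rtol=1e-9)

    def test_seed_reproducibility(self, spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = tk.run_psa(spec, n_iter=50, seed=42)
            b = tk.run_psa(spec, n_iter=50, seed=42)
        for arm in spec.arm_names:
            assert np.array_equal(a.cost[arm], b.cost[arm])
            assert np.array_equal(a.qaly[arm], b.qaly[arm])

    def test_mean_psa_increment_tracks_deterministic(self, spec, base_results, psa_small):
        det_inc = (base_results["dasatinib"].total_cost
                   - base_results["imatinib"].total_cost)
        assert psa_small.inc_cost.mean() == pytest.approx(det_inc, rel=0.10)

    def test_ceac_matches_ce_plane_identity(self, psa_small):
        for wtp in (0.0, 18_882.0, 37_765.0, 1e9):
            plane = tk.ce_plane(psa_small, wtp=wtp)
            assert plane["below_wtp_line"].mean() == psa_small.prob_cost_effective(wtp)

    def test_ceac_limits(self, psa_small):
        lo = psa_small.prob_cost_effective(0.0)
        assert lo == np.mean(psa_small.inc_cost < 0.0)  # WTP 0: pure cost race
        hi = psa_small.prob_cost_effective(1e12)
        assert hi == np.mean(psa_small.inc_qaly > 0.0)  # huge WTP: pure QALY race
        curve = tk.ceac(psa_small, np.linspace(0, 1e5, 11))
        assert np.all((0.0 <= curve["probability"]) & (curve["probability"] <= 1.0))

    def test_quadrants_partition_iterations(self, psa_small):
        counts = quadrant_counts(psa_small)
        assert sum(counts.values()) == psa_small.n_iter

    def test_invalid_n_iter(self, spec):
        with pytest.raises(ValueError):
            tk.run_psa(spec, n_iter=0, seed=1)
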