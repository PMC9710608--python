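"""Abundance/partition sampling, back-calculation, allostery, anchoring."""

import numpy as np
import pytest
from scipy import stats

import kinensemble as ke
from kinensemble.param_sampling import AllostericParams
from kinensemble.thermo import R_GAS

UNI = dict(substrates=[("S", 1.0)], products=[("P", 1.0)])


class TestAbundances:
    def test_simplex_and_positivity(self):
        pat = ke.build_pattern("uniUni", "r", **UNI)
        e = ke.sample_abundances(pat, np.random.default_rng(0))
        assert e.sum() == pytest.approx(1.0)
        assert (e > 0).all()

    def test_flat_dirichlet_moments(self):
        pat = ke.build_pattern("uniUni", "r", **UNI)
        rng = np.random.default_rng(1)
        draws = np.array([ke.sample_abundances(pat, rng) for _ in range(10000)])
        se = np.sqrt((1 / 3) * (2 / 3) / 4 / draws.shape[0])
        assert np.abs(draws.mean(axis=0) - 1 / 3).max() < 3 * se

    def test_degenerate_single_state(self):
        pat = ke.MechanismPattern(["r"], ["E"], [], {"r": []}, {"r": 0})
        np.testing.assert_array_equal(ke.sample_abundances(pat, np.random.default_rng(2)),
                                      [1.0])


class TestPartition:
    def test_product_of_step_reversibilities_is_overall(self):
        pat = ke.build_pattern("orderedBiBi", "r",
                               substrates=[("A", 1.0), ("B", 1.0)],
                               products=[("P", 1.0), ("Q", 1.0)])
        rng = np.random.default_rng(3)
        for dg in (-12.0, -0.5, 6.0):
            zeta, step_r = ke.partition_reversibility(dg, pat, rng)
            cyc = pat.cycles["r"]
            assert np.nansum(zeta[cyc]) == pytest.approx(1.0, abs=1e-12)
            overall = np.exp(dg / (R_GAS * 298.15))
            assert np.prod(step_r[cyc]) == pytest.approx(overall, rel=1e-12)
            side = 1.0 if dg > 0 else -1.0
            assert all(side * (step_r[i] - 1.0) > 0 for i in cyc)

    def test_dead_end_steps_get_no_partition_mass(self):
        pat = ke.build_pattern("uniUni", "r", inhibitors=["I"], **UNI)
        zeta, step_r = ke.partition_reversibility(-5.0, pat, np.random.default_rng(4))
        inh = [i for i, s in enumerate(pat.steps) if s.is_inhibitor]
        assert np.isnan(zeta[inh]).all() and np.isnan(step_r[inh]).all()

    def test_branched_paths_obey_loop_condition(self):
        pat = ke.build_pattern("randomBiBi", "r",
                               substrates=[("A", 1.0), ("B", 1.0)],
                               products=[("P", 1.0), ("Q", 1.0)])
        zeta, step_r = ke.partition_reversibility(-9.0, pat, np.random.default_rng(5))
        main, alt = pat.branches["r"][0]
        assert np.prod(step_r[main]) == pytest.approx(np.prod(step_r[alt]), rel=1e-12)


class TestBackCalculation:
    def test_one_way_flux_decomposition_formulas(self):
        """w+ = v/(1-r), w- = v·r/(1-r); k's divide by the state abundances."""
        pat = ke.build_pattern("uniUni", "r", **UNI)
        e_ref = np.array([0.5, 0.3, 0.2])
        step_r = np.array([0.5, 0.25, 0.8])
        kp, km = ke.back_calculate_constants(pat, {"r": 1.0}, e_ref, step_r,
                                             np.random.default_rng(0))
        pos = {s: i for i, s in enumerate(pat.states)}
        for i, st in enumerate(pat.steps):
            w_f = 1.0 / (1.0 - step_r[i])
            assert kp[i] == pytest.approx(w_f / e_ref[pos[st.source]], rel=1e-12)
            assert km[i] == pytest.approx(w_f * step_r[i] / e_ref[pos[st.target]], rel=1e-12)
        # worked case: v=1, r=0.5 and equal abundances 0.5 gives w+=2, w-=1
        assert 1.0 / (1.0 - 0.5) / 0.5 == pytest.approx(4.0)   # k_plus
        assert (1.0 * 0.5 / (1.0 - 0.5)) / 0.5 == pytest.approx(2.0)  # k_minus

    def test_flux_reversal_swaps_one_way_fluxes(self):
        pat = ke.build_pattern("uniUni", "r", **UNI)
        e_ref = np.array([0.4, 0.35, 0.25])
        r = np.array([0.5, 0.2, 0.7])
        kp_f, km_f = ke.back_calculate_constants(pat, {"r": 2.0}, e_ref, r,
                                                 np.random.default_rng(0))
        kp_r, km_r = ke.back_calculate_constants(pat, {"r": -2.0}, e_ref, 1.0 / r,
                                                 np.random.default_rng(0))
        pos = {s: i for i, s in enumerate(pat.states)}
        for i, st in enumerate(pat.steps):
            a, b = pos[st.source], pos[st.target]
            # forward one-way flux of the reversed reaction = reverse of the original
            assert kp_r[i] * e_ref[a] == pytest.approx(km_f[i] * e_ref[b], rel=1e-12)
            assert km_r[i] * e_ref[b] == pytest.approx(kp_f[i] * e_ref[a], rel=1e-12)

    def test_zero_flux_steps_get_positive_equilibrium_turnover(self):
        pat = ke.build_pattern("uniUni", "r", **UNI)
        e_ref = np.array([0.5, 0.3, 0.2])
        step_r = np.full(3, np.nan)
        kp, km = ke.back_calculate_constants(pat, {"r": 0.0}, e_ref, step_r,
                                             np.random.default_rng(1))
        assert (kp > 0).all() and (km > 0).all()
        fn = ke.RateFunction(pat, kp, km)
        assert fn({"S": 1.0, "P": 1.0})["r"] == pytest.approx(0.0, abs=1e-12)


class TestAllostery:
    def test_log_L_uniform_by_ks_test(self):
        rng = np.random.default_rng(6)
        draws = np.array([ke.sample_allostery(((), ()), rng).L for _ in range(10000)])
        stat = stats.kstest(np.log10(draws), stats.uniform(loc=-4, scale=8).cdf)
        assert stat.pvalue > 0.01

    def test_reproducible_given_seed(self):
        a = ke.sample_allostery((("x",), ("y",)), np.random.default_rng(9))
        b = ke.sample_allostery((("x",), ("y",)), np.random.default_rng(9))
        assert (a.L, a.n_protomers, a.K_act, a.K_inh) == (b.L, b.n_protomers, b.K_act, b.K_inh)

    def test_factor_limits(self):
        no_t_state = AllostericParams(L=0.0, n_protomers=2)
        assert ke.regulatory_factor(no_t_state, {}, {}) == 1.0
        all_tense = AllostericParams(L=1e300, n_protomers=1)
        assert ke.regulatory_factor(all_tense, {}, {}) == pytest.approx(0.0, abs=1e-12)
        act = AllostericParams(L=1.0, n_protomers=2, K_act={"a": 1.0})
        assert ke.regulatory_factor(act, {"a": 1e12}, {}) == pytest.approx(1.0, rel=1e-6)

    def test_monotone_in_effectors(self):
        allo = AllostericParams(L=2.0, n_protomers=3, K_act={"a": 0.5}, K_inh={"i": 2.0})
        grid = [0.0, 0.5, 1.0, 4.0]
        f_act = [ke.regulatory_factor(allo, {"a": c}, {"i": 1.0}) for c in grid]
        f_inh = [ke.regulatory_factor(allo, {"a": 1.0}, {"i": c}) for c in grid]
        assert all(x < y for x, y in zip(f_act, f_act[1:]))
        assert all(x > y for x, y in zip(f_inh, f_inh[1:]))
        with pytest.raises(ValueError):
            ke.regulatory_factor(allo, {"a": -1.0}, {})


class TestEndToEnd:
    def test_every_sampled_model_is_anchored_and_haldane_consistent(
            self, chain_bundle, chain_ensemble):
        model = chain_bundle.model
        for p in chain_ensemble.models:
            rates = ke.ModelRates(model, p)
            v = p.thermo.v_resolved
            got = rates.reference_rates()
            np.testing.assert_allclose(got, v, rtol=1e-9)
            rt = R_GAS * p.thermo.temperature
            for eid, u in p.enzyme_units.items():
                fn = u.rate_function()
                for rid in u.pattern.reaction_ids:
                    j = model.rxn_index[rid]
                    if v[j] == 0:
                        continue
                    assert fn.haldane_product(rid) == pytest.approx(
                        np.exp(-p.thermo.dG[j] / rt), rel=1e-9)

    def test_anchoring_holds_with_regulation_active(self):
        bundle = ke.make_linear_chain(3, rng=8, allosteric_inhibition=("r_1", "m_2"),
                                      competitive_inhibition=("r_2", "m_1"))
        ens = ke.sample_prior_ensemble(bundle.model, bundle.ref,
                                       ke.SamplingConfig(n_models=5, seed=21))
        for p in ens.models:
            assert p.allosteric  # the interaction was sampled
            got = ke.ModelRates(bundle.model, p).reference_rates()
            np.testing.assert_allclose(got, p.thermo.v_resolved, rtol=1e-9)

    def test_abc_concentrates_around_truth_as_tolerance_shrinks(self):
        """Accepted elementary constants drift toward the truth as the ABC
        tolerance tightens (parameter-recovery property on noiseless data)."""
        import dataclasses
        from kinensemble.ensemble import _model_rng, _evaluate_attempt
        from kinensemble.param_sampling import build_model_patterns
        from kinensemble.thermo import tighten_dg_bounds

        bundle = ke.make_linear_chain(3, rng=14)
        bundle.config = ke.SamplingConfig(n_models=5, seed=bundle.seed)
        obs = ke.generate_observations(bundle, [{"r_1": 1.6}], noise_sd=0.0, rng=2)
        truth = bundle.truth

        def flat_k(p):
            return np.concatenate([np.concatenate([u.k_plus, u.k_minus])
                                   for u in p.enzyme_units.values()])

        tight = tighten_dg_bounds(bundle.model, bundle.ref)
        pats = build_model_patterns(bundle.model)
        cfg = dataclasses.replace(bundle.config, mode="rejection", tolerance=np.inf)
        draws = []
        for i in range(15):
            p, d = _evaluate_attempt(bundle.model, tight, pats, obs, cfg,
                                     _model_rng(bundle.seed, i))
            draws.append((d, np.median(np.abs(np.log(flat_k(p) / flat_k(truth))))))
        dist = np.array([d for d, _ in draws])
        err = np.array([e for _, e in draws])
        # tolerance -> 0: only the truth-generating draw survives (error 0);
        # tolerance -> inf: the whole prior, with substantial error
        err_tight = np.median(err[dist <= 1e-9])
        err_loose = np.median(err)
        assert err_tight == pytest.approx(0.0, abs=1e-12)
        assert err_loose > 0.1
        assert err_tight < err_loose
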