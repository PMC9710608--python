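"""Prior ensembles, ABC distance and rejection, model selection, serialization."""

import dataclasses
import math

import numpy as np
import pytest

import kinensemble as ke
from kinensemble.ensemble import PredictedState, _model_rng


def _flat_k(p):
    return np.concatenate([np.concatenate([u.k_plus, u.k_minus])
                           for u in p.enzyme_units.values()])


class TestPriorEnsemble:
    def test_exact_count_all_anchored(self, chain_bundle, chain_ensemble):
        assert chain_ensemble.n_accepted == 10
        for p in chain_ensemble.models:
            got = ke.ModelRates(chain_bundle.model, p).reference_rates()
            np.testing.assert_allclose(got, p.thermo.v_resolved, rtol=1e-9)

    def test_same_seed_reproduces_bitwise(self, chain_bundle, chain_ensemble):
        again = ke.sample_prior_ensemble(chain_bundle.model, chain_bundle.ref,
                                         ke.SamplingConfig(n_models=10, seed=7))
        for a, b in zip(chain_ensemble.models, again.models):
            np.testing.assert_array_equal(_flat_k(a), _flat_k(b))
            np.testing.assert_array_equal(a.thermo.dG, b.thermo.dG)

    def test_different_seeds_differ(self, chain_bundle, chain_ensemble):
        other = ke.sample_prior_ensemble(chain_bundle.model, chain_bundle.ref,
                                         ke.SamplingConfig(n_models=10, seed=8))
        assert not np.array_equal(_flat_k(chain_ensemble.models[0]),
                                  _flat_k(other.models[0]))

    def test_counter_seeding_is_partition_independent(self, chain_bundle, chain_ensemble):
        """Model i depends only on (seed, i): sampling a shorter ensemble gives
        a prefix of the longer one, as a parallel scheduler would produce."""
        short = ke.sample_prior_ensemble(chain_bundle.model, chain_bundle.ref,
                                         ke.SamplingConfig(n_models=3, seed=7))
        for a, b in zip(short.models, chain_ensemble.models[:3]):
            np.testing.assert_array_equal(_flat_k(a), _flat_k(b))


class TestPredictCondition:
    def test_identity_folds_return_reference(self, chain_bundle, chain_ensemble):
        p = chain_ensemble.models[0]
        cond = ke.Condition("ref", enzyme_folds={}, fluxes={"r_1": (1.0, 0.1)})
        pred = ke.predict_condition(chain_bundle.model, p, cond)
        assert pred.converged
        np.testing.assert_allclose(pred.fluxes, p.thermo.v_resolved, atol=1e-7)
        np.testing.assert_allclose(pred.conc, 1.0, atol=1e-7)

    def test_overexpressing_first_enzyme_raises_chain_flux(self, chain_bundle, chain_ensemble):
        p = chain_ensemble.models[1]
        cond = ke.Condition("up", enzyme_folds={"r_1": 2.0}, fluxes={"r_1": (1.0, 0.1)})
        pred = ke.predict_condition(chain_bundle.model, p, cond)
        assert pred.converged
        assert (pred.fluxes > p.thermo.v_resolved + 1e-6).all()

    def test_knockout_of_essential_enzyme_kills_flux(self, chain_bundle, chain_ensemble):
        p = chain_ensemble.models[2]
        cond = ke.Condition("ko", enzyme_folds={"r_2": 0.0}, fluxes={"r_1": (1.0, 0.1)})
        cfg = ke.SamplingConfig(t_end=5000.0)
        pred = ke.predict_condition(chain_bundle.model, p, cond, cfg)
        j = chain_bundle.model.rxn_index["r_2"]
        assert abs(pred.fluxes[j]) < 1e-6


class TestDistance:
    @pytest.fixture()
    def simple_obs(self, chain_bundle):
        return ke.ObservationSet([
            ke.Condition("c0", fluxes={"r_1": (1.0, 0.5)},
                         concentrations={"m_1": (1.0, 0.2)}),
        ])

    def _pred(self, model, fluxes, conc):
        return PredictedState(np.asarray(fluxes, dtype=float),
                              np.asarray(conc, dtype=float), True)

    def test_zero_iff_exact_match(self, chain_bundle, simple_obs):
        model = chain_bundle.model
        pred = self._pred(model, np.ones(4), np.ones(5))
        assert ke.abc_distance({"c0": pred}, simple_obs, model) == 0.0

    def test_two_sigma_residual_gives_distance_two(self, chain_bundle):
        model = chain_bundle.model
        obs = ke.ObservationSet([ke.Condition("c0", fluxes={"r_1": (1.0, 0.5)})])
        pred = self._pred(model, [2.0, 1, 1, 1], np.ones(5))
        assert ke.abc_distance({"c0": pred}, obs, model) == pytest.approx(2.0)

    def test_duplicated_condition_leaves_rms_unchanged(self, chain_bundle, simple_obs):
        model = chain_bundle.model
        pred = self._pred(model, [1.4, 1, 1, 1], [1, 0.8, 1, 1, 1])
        d1 = ke.abc_distance({"c0": pred}, simple_obs, model)
        doubled = ke.ObservationSet([
            simple_obs.conditions[0],
            dataclasses.replace(simple_obs.conditions[0], name="c1"),
        ])
        d2 = ke.abc_distance({"c0": pred, "c1": pred}, doubled, model)
        assert d2 == pytest.approx(d1, rel=1e-12)

    def test_divergent_prediction_is_infinitely_far(self, chain_bundle, simple_obs):
        model = chain_bundle.model
        pred = PredictedState(np.full(4, np.nan), np.full(5, np.nan), False)
        assert math.isinf(ke.abc_distance({"c0": pred}, simple_obs, model))

    def test_empty_overlap_raises(self, chain_bundle):
        model = chain_bundle.model
        obs = ke.ObservationSet([ke.Condition("c9", fluxes={"r_1": (1.0, 0.5)})])
        with pytest.raises(ValueError, match="overlap"):
            ke.abc_distance({}, obs, model)


@pytest.fixture(scope="module")
def noiseless():
    bundle = ke.make_linear_chain(3, rng=4)
    bundle.config = ke.SamplingConfig(n_models=3, seed=bundle.seed)
    obs = ke.generate_observations(bundle, [{"r_1": 1.5}, {"r_2": 0.7}],
                                   noise_sd=0.0, rng=0)
    return bundle, obs


class TestRejection:

    def test_infinite_tolerance_reproduces_prior(self, noiseless):
        bundle, obs = noiseless
        cfg = dataclasses.replace(bundle.config, mode="rejection",
                                  tolerance=math.inf, n_models=3)
        ens = ke.abc_rejection(bundle.model, bundle.ref, obs, cfg)
        prior = ke.sample_prior_ensemble(bundle.model, bundle.ref,
                                         dataclasses.replace(bundle.config, n_models=3))
        assert ens.n_accepted == ens.n_attempted == 3
        for a, b in zip(ens.models, prior.models):
            np.testing.assert_array_equal(_flat_k(a), _flat_k(b))

    def test_truth_draw_accepted_with_zero_distance(self, noiseless):
        bundle, obs = noiseless
        cfg = dataclasses.replace(bundle.config, mode="rejection",
                                  tolerance=1e-9, n_models=1, max_attempts=1)
        ens = ke.abc_rejection(bundle.model, bundle.ref, obs, cfg)
        assert ens.n_accepted == 1
        assert ens.distances[0] == pytest.approx(0.0, abs=1e-9)

    def test_acceptance_monotone_in_tolerance_on_fixed_stream(self, noiseless):
        bundle, obs = noiseless
        cfg = dataclasses.replace(bundle.config, mode="rejection", tolerance=math.inf)
        full = ke.abc_rejection(bundle.model, bundle.ref, obs, cfg,
                                n_attempts=12, stop_at_n_models=False)
        d = np.array(full.distances)
        counts = [(d <= tol).sum() for tol in (0.5, 2.0, 8.0)]
        assert counts == sorted(counts)
        assert counts[0] >= 1   # the truth draw sits in the stream

    def test_no_acceptance_reports_best_distance(self, noiseless):
        bundle, obs = noiseless
        cfg = dataclasses.replace(bundle.config, mode="rejection",
                                  tolerance=1e-12, n_models=1, seed=999)
        with pytest.raises(RuntimeError, match="best distance"):
            ke.abc_rejection(bundle.model, bundle.ref, obs, cfg, n_attempts=3)


class TestModelSelection:
    def test_identical_candidates_get_identical_rates(self):
        bundle = ke.make_linear_chain(3, rng=4)
        bundle.config = ke.SamplingConfig(n_models=3, seed=bundle.seed)
        obs = ke.generate_observations(bundle, [{"r_1": 1.5}], noise_sd=0.0, rng=0)
        cfg = dataclasses.replace(bundle.config, mode="rejection", tolerance=5.0)
        df = ke.model_selection([("a", bundle.model, bundle.ref),
                                 ("b", bundle.model, bundle.ref)], obs, cfg,
                                n_attempts=8)
        assert df.loc[0, "n_accepted"] == df.loc[1, "n_accepted"]

    def test_infeasible_candidate_scores_zero(self):
        bundle = ke.make_linear_chain(3, rng=4)
        bundle.config = ke.SamplingConfig(n_models=3, seed=bundle.seed)
        obs = ke.generate_observations(bundle, [{"r_1": 1.5}], noise_sd=0.0, rng=0)
        bad_ref = bundle.ref.copy()
        bad_ref.dG_range[0] = (2.0, 10.0)   # excludes the required sign
        cfg = dataclasses.replace(bundle.config, mode="rejection", tolerance=5.0)
        df = ke.model_selection([("ok", bundle.model, bundle.ref),
                                 ("infeasible", bundle.model, bad_ref)], obs, cfg,
                                n_attempts=6)
        assert df.set_index("candidate").loc["infeasible", "acceptance_rate"] == 0.0
        assert df.set_index("candidate").loc["ok", "n_accepted"] > 0

    def test_true_allosteric_structure_is_preferred(self):
        """Data carry a real feedback inhibition; the candidate including it
        must reach at least the acceptance rate of the one lacking it."""
        truth_b = ke.make_linear_chain(3, rng=10, allosteric_inhibition=("r_1", "m_2"))
        truth_b.config = ke.SamplingConfig(n_models=5, seed=truth_b.seed)
        obs = ke.generate_observations(truth_b, [{"r_3": 2.0}, {"r_2": 0.5}],
                                       noise_sd=0.05, rng=1)
        alt_b = ke.make_linear_chain(3, rng=10)
        cfg = dataclasses.replace(truth_b.config, mode="rejection",
                                  tolerance=8.0, seed=123)
        df = ke.model_selection(
            [("with_allostery", truth_b.model, truth_b.ref),
             ("without", alt_b.model, alt_b.ref)], obs, cfg, n_attempts=30)
        rates = df.set_index("candidate")["acceptance_rate"]
        assert rates["with_allostery"] >= rates["without"]
        assert rates["with_allostery"] > 0


class TestSerialization:
    def test_ensemble_round_trip(self, tmp_path, chain_bundle, chain_ensemble):
        path = ke.save_ensemble(chain_ensemble, tmp_path / "ens.json")
        loaded = ke.load_ensemble(path, chain_bundle.model)
        assert loaded.n_accepted == chain_ensemble.n_accepted
        assert loaded.seed == chain_ensemble.seed
        for a, b in zip(chain_ensemble.models, loaded.models):
            np.testing.assert_array_equal(_flat_k(a), _flat_k(b))
            got = ke.ModelRates(chain_bundle.model, b).reference_rates()
            np.testing.assert_allclose(got, a.thermo.v_resolved, rtol=1e-9)

    def test_observations_tsv_round_trip(self, tmp_path):
        obs = ke.ObservationSet([
            ke.Condition("c0", enzyme_folds={"r_1": 1.5},
                         fluxes={"r_1": (0.9, 0.1)},
                         concentrations={"m_1": (1.2, 0.05)},
                         enzymes_measured={"r_1": (1.4, 0.2)}),
        ])
        d = ke.write_observations(obs, tmp_path / "obs")
        back = ke.read_observations(d)
        c = back.conditions[0]
        assert c.enzyme_folds == {"r_1": 1.5}
        assert c.fluxes == {"r_1": (0.9, 0.1)}
        assert c.concentrations == {"m_1": (1.2, 0.05)}
        assert c.enzymes_measured == {"r_1": (1.4, 0.2)}
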