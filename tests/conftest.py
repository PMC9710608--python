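import numpy as np
import pytest

import kinensemble as ke


@pytest.fixture(scope="session")
def chain_bundle():
    return ke.make_linear_chain(4, rng=1)


@pytest.fixture(scope="session")
def chain_ensemble(chain_bundle):
    cfg = ke.SamplingConfig(n_models=10, seed=7)
    return ke.sample_prior_ensemble(chain_bundle.model, chain_bundle.ref, cfg)


@pytest.fixture(scope="session")
def casestudy_bundle():
    return ke.make_casestudy_shape(rng=3)


@pytest.fixture(scope="session")
def casestudy_ensemble(casestudy_bundle):
    cfg = ke.SamplingConfig(n_models=3, seed=11)
    return ke.sample_prior_ensemble(casestudy_bundle.model, casestudy_bundle.ref, cfg)


@pytest.fixture(scope="session")
def cofactor_bundle():
    """Small pathway with a conserved NAD/NADH pool: one bi-bi step plus a
    mass-action regeneration closing the cofactor loop."""
    mets = [
        ke.Metabolite("x_in", balanced=False),
        ke.Metabolite("a"), ke.Metabolite("b"),
        ke.Metabolite("nad"), ke.Metabolite("nadh"),
        ke.Metabolite("x_out", balanced=False),
    ]
    rxns = [
        ke.Reaction("r_in", ke.MASS_ACTION),
        ke.Reaction("r_dh", "orderedBiBi"),
        ke.Reaction("r_out", ke.MASS_ACTION),
        ke.Reaction("r_regen", ke.MASS_ACTION),
    ]
    S = np.zeros((6, 4))
    mi = {m.id: i for i, m in enumerate(mets)}
    for m, r, c in [("x_in", 0, -1), ("a", 0, 1),
                    ("a", 1, -1), ("nad", 1, -1), ("b", 1, 1), ("nadh", 1, 1),
                    ("b", 2, -1), ("x_out", 2, 1),
                    ("nadh", 3, -1), ("nad", 3, 1)]:
        S[mi[m], r] = c
    model = ke.NetworkModel(mets, rxns, S)
    ref = ke.ReferenceState(
        v_ref=np.ones(4),
        dG_range=np.tile([-20.0, -1.0], (4, 1)),
        conc_range=np.tile([1e-4, 1e-2], (6, 1)),
    )
    return ke.FixtureBundle(model, ref, ke.SamplingConfig(n_models=3, seed=5), seed=5)
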