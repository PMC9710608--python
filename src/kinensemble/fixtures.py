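"""Synthetic toy networks, reference states, and ground-truth observations.

Everything other modules need for testing is generated here programmatically:
no downloads, no stored data files.  Two network families are provided:

* a boundary-fed linear pathway of uni-uni enzymes (`make_linear_chain`),
  the minimal system with non-trivial control structure;
* a case-study-shaped network (`make_casestudy_shape`) with 79 reactions —
  27 mass-action exchange/regeneration reactions and 52 mechanistic reactions
  including one isoenzyme pair, seven promiscuous enzymes, competitive
  inhibitors, allosteric effectors, a shared cofactor pool (conserved moiety)
  and all four built-in mechanisms — exercising every model construct at once.

Reference fluxes are consistent steady states by construction; Gibbs-energy
ranges are strictly negative for flux-carrying reactions, so every bundle
passes validation with zero errors.  `generate_observations` simulates a
known-truth parameterization under enzyme-fold-change conditions and emits
noisy (or noiseless) fluxes and log-concentrations for ABC tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ensemble import Condition, ObservationSet, _model_rng, predict_condition
from .model_io import (
    MASS_ACTION, Metabolite, NetworkModel, Reaction, ReferenceState,
    SamplingConfig, write_model_spec,
)
from .param_sampling import KineticParameterization, build_model_patterns, sample_parameterization
from .thermo import sample_thermo_state, tighten_dg_bounds


@dataclass
class FixtureBundle:
    model: NetworkModel
    ref: ReferenceState
    config: SamplingConfig
    seed: int = 0
    truth: KineticParameterization | None = None
    observations: ObservationSet | None = None
    path: Path | None = None

    def write(self, path: str | Path) -> Path:
        self.path = write_model_spec(self.model, self.ref, self.config, path)
        return self.path


def _network(mets, rxns, entries) -> NetworkModel:
    """Assemble a NetworkModel from sparse (met, rxn, coeff) entries."""
    met_ids = [m.id for m in mets]
    rxn_ids = [r.id for r in rxns]
    S = np.zeros((len(mets), len(rxns)))
    mi = {m: i for i, m in enumerate(met_ids)}
    ri = {r: j for j, r in enumerate(rxn_ids)}
    for m, r, c in entries:
        S[mi[m], ri[r]] += c
    return NetworkModel(mets, rxns, S)


# ---------------------------------------------------------------------------
# linear chain
# ---------------------------------------------------------------------------

def make_linear_chain(n_reactions: int, flux: float = 1.0,
                      rng: np.random.Generator | int | None = None,
                      dg_range: tuple[float, float] = (-25.0, -1.0),
                      conc_range: tuple[float, float] = (5e-5, 5e-3),
                      allosteric_inhibition: tuple[str, str] | None = None,
                      competitive_inhibition: tuple[str, str] | None = None,
                      ) -> FixtureBundle:
    """Boundary-fed linear pathway m_0 -> m_1 -> ... -> m_n, all uni-uni.

    ``m_0`` and ``m_n`` are fixed boundary metabolites; every reaction carries
    the same reference flux (steady state by construction) and a strictly
    negative Gibbs-energy range.  Optional regulator hooks add an allosteric
    or competitive interaction (reaction id, metabolite id) for model-selection
    fixtures.
    """
    if n_reactions < 2:
        raise ValueError("a chain needs at least 2 reactions")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = n_reactions
    mets = [Metabolite("m_0", balanced=False)]
    mets += [Metabolite(f"m_{i}") for i in range(1, n)]
    mets.append(Metabolite(f"m_{n}", balanced=False))
    rxns = []
    for j in range(1, n + 1):
        kwargs = {}
        if allosteric_inhibition and allosteric_inhibition[0] == f"r_{j}":
            kwargs["neg_effectors"] = (allosteric_inhibition[1],)
        if competitive_inhibition and competitive_inhibition[0] == f"r_{j}":
            kwargs["inhibitors"] = (competitive_inhibition[1],)
        rxns.append(Reaction(f"r_{j}", "uniUni", **kwargs))
    entries = []
    for j in range(1, n + 1):
        entries.append((f"m_{j-1}", f"r_{j}", -1.0))
        entries.append((f"m_{j}", f"r_{j}", 1.0))
    model = _network(mets, rxns, entries)

    n_m = len(mets)
    ref = ReferenceState(
        v_ref=np.full(n, float(flux)),
        dG_range=np.tile(np.asarray(dg_range, dtype=float), (n, 1)),
        conc_range=np.tile(np.asarray(conc_range, dtype=float), (n_m, 1)),
    )
    seed = int(rng.integers(0, 2**31 - 1))
    return FixtureBundle(model, ref, SamplingConfig(n_models=10, seed=seed), seed=seed)


# ---------------------------------------------------------------------------
# case-study-shaped network
# ---------------------------------------------------------------------------

N_PATHWAYS = 13


def make_casestudy_shape(rng: np.random.Generator | int | None = None) -> FixtureBundle:
    """Synthetic network reproducing the structural shape of a genome-scale-
    derived central-metabolism model: 79 reactions (27 mass-action exchange/
    regeneration + 52 mechanistic), one isoenzyme pair, seven promiscuous
    enzymes, competitive inhibitors and allosteric effectors, and a conserved
    cofactor pool.  Kinetic content is synthetic; only the shape is fixed.

    Thirteen parallel pathways connect boundary metabolites through 3-4
    mechanistic steps each; three pathways couple to a shared NAD/NADH pool
    (ordered, random and ping-pong bi-bi mechanisms) closed by one mass-action
    regeneration reaction.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    entries: list[tuple[str, str, float]] = []
    flux: dict[str, float] = {}

    mets += [Metabolite("nad"), Metabolite("nadh")]
    pathway_flux = {p: round(0.5 + 0.1 * p, 3) for p in range(1, N_PATHWAYS + 1)}

    # per-pathway metabolites: pathway 1 has 4 internal nodes (iso pair shares
    # one step), others 5
    n_nodes = {p: (4 if p == 1 else 5) for p in range(1, N_PATHWAYS + 1)}
    for p in range(1, N_PATHWAYS + 1):
        mets.append(Metabolite(f"x_in_{p}", balanced=False))
        mets.append(Metabolite(f"x_out_{p}", balanced=False))
        for k in range(1, n_nodes[p] + 1):
            mets.append(Metabolite(f"s_{p}_{k}"))

    def add(rid, subs, prods, v, mechanism="uniUni", **kw):
        rxns.append(Reaction(rid, mechanism, **kw))
        for m, c in subs:
            entries.append((m, rid, -c))
        for m, c in prods:
            entries.append((m, rid, c))
        flux[rid] = v

    # exchanges (mass action): 2 per pathway = 26
    for p in range(1, N_PATHWAYS + 1):
        f = pathway_flux[p]
        add(f"r_in_{p}", [(f"x_in_{p}", 1.0)], [(f"s_{p}_1", 1.0)], f, MASS_ACTION)
        add(f"r_out_{p}", [(f"s_{p}_{n_nodes[p]}", 1.0)], [(f"x_out_{p}", 1.0)], f, MASS_ACTION)

    # pathway 1: isoenzyme pair on the first step, then 2 uni-uni steps;
    # allosteric inhibition of both isoenzymes by the pathway end product
    f1 = pathway_flux[1]
    add("r_pyk1", [("s_1_1", 1.0)], [("s_1_2", 1.0)], np.nan,
        isoenzyme_group="g_pyk", neg_effectors=("s_1_4",))
    add("r_pyk2", [("s_1_1", 1.0)], [("s_1_2", 1.0)], np.nan,
        isoenzyme_group="g_pyk", neg_effectors=("s_1_4",))
    add("r_1_2", [("s_1_2", 1.0)], [("s_1_3", 1.0)], f1)
    add("r_1_3", [("s_1_3", 1.0)], [("s_1_4", 1.0)], f1)

    # pathways 2..13: 4 mechanistic steps each; step 2 of pathways 2-4 couples
    # to the NAD pool with the three bi-bi mechanisms
    cofactor_mech = {2: "orderedBiBi", 3: "randomBiBi", 4: "pingPong"}
    for p in range(2, N_PATHWAYS + 1):
        f = pathway_flux[p]
        kw1: dict = {}
        if p == 2:
            kw1["inhibitors"] = ("s_1_3",)        # competitive inhibitor
        if p == 6:
            kw1["activators"] = ("s_3_3",)        # allosteric activator
        add(f"r_{p}_1", [(f"s_{p}_1", 1.0)], [(f"s_{p}_2", 1.0)], f, **kw1)
        kw2: dict = {}
        if p == 5:
            kw2["inhibitors"] = ("s_2_3",)
        if p in cofactor_mech:
            add(f"r_{p}_2", [(f"s_{p}_2", 1.0), ("nad", 1.0)],
                [(f"s_{p}_3", 1.0), ("nadh", 1.0)], f, cofactor_mech[p], **kw2)
        else:
            add(f"r_{p}_2", [(f"s_{p}_2", 1.0)], [(f"s_{p}_3", 1.0)], f, **kw2)
        # steps 3 and 4: uni-uni; step-3 pairs and one step-4 pair form the
        # seven promiscuous enzymes
        prom = None
        if p >= 2:
            prom = f"g_prom_{(p - 2) // 2 + 1}" if p <= 13 and (p - 2) // 2 < 6 else None
        add(f"r_{p}_3", [(f"s_{p}_3", 1.0)], [(f"s_{p}_4", 1.0)], f,
            promiscuous_group=prom)
        prom4 = "g_prom_7" if p in (2, 3) else None
        add(f"r_{p}_4", [(f"s_{p}_4", 1.0)], [(f"s_{p}_5", 1.0)], f,
            promiscuous_group=prom4)

    # cofactor regeneration (mass action, reversible): nadh -> nad
    regen_flux = pathway_flux[2] + pathway_flux[3] + pathway_flux[4]
    add("r_regen", [("nadh", 1.0)], [("nad", 1.0)], regen_flux, MASS_ACTION)

    model = _network(mets, rxns, entries)
    n_r, n_m = model.n_reactions, model.n_metabolites

    v_ref = np.array([flux[r.id] for r in rxns])
    dG_range = np.tile(np.array([-25.0, -1.0]), (n_r, 1))
    dG_range += rng.uniform(-2.0, 0.0, size=(n_r, 1))  # mild per-reaction variation
    conc_range = np.tile(np.array([5e-5, 5e-3]), (n_m, 1))
    ref = ReferenceState(v_ref=v_ref, dG_range=dG_range, conc_range=conc_range,
                         group_flux={"g_pyk": f1})
    seed = int(rng.integers(0, 2**31 - 1))
    return FixtureBundle(model, ref, SamplingConfig(n_models=5, seed=seed), seed=seed)


def audit_casestudy(bundle: FixtureBundle) -> dict[str, int]:
    """Structural counts of the case-study-shaped fixture."""
    model = bundle.model
    n_ma = sum(1 for r in model.reactions if r.mechanism == MASS_ACTION)
    iso = model.isoenzyme_groups()
    return {
        "n_reactions": model.n_reactions,
        "n_mass_action": n_ma,
        "n_mechanistic": model.n_reactions - n_ma,
        "n_promiscuous_enzymes": len(model.promiscuous_groups()),
        "n_isoenzyme_groups": len(iso),
        "n_isoenzymes": sum(len(m) for m in iso.values()),
        "n_competitive_inhibitors": sum(len(r.inhibitors) for r in model.reactions),
        "n_allosteric_effectors": sum(len(r.activators) + len(r.neg_effectors)
                                      for r in model.reactions),
    }


# ---------------------------------------------------------------------------
# ground-truth observations
# ---------------------------------------------------------------------------

def attach_truth(bundle: FixtureBundle, seed: int | None = None) -> KineticParameterization:
    """Sample and attach a known-truth parameterization (the attempt-0 draw of
    the bundle's seed, so ABC on the same seed path re-derives it exactly)."""
    s = bundle.seed if seed is None else seed
    rng = _model_rng(s, 0)
    tightened = tighten_dg_bounds(bundle.model, bundle.ref)
    ts = sample_thermo_state(bundle.model, tightened, rng,
                             max_tries=bundle.config.thermo_max_tries)
    patterns = build_model_patterns(bundle.model)
    bundle.truth = sample_parameterization(bundle.model, patterns, ts,
                                           bundle.config, rng)
    return bundle.truth


def generate_observations(bundle: FixtureBundle,
                          conditions: list[dict[str, float]],
                          noise_sd: float,
                          rng: np.random.Generator | int | None = None,
                          measure_fluxes: list[str] | None = None,
                          measure_concs: list[str] | None = None) -> ObservationSet:
    """Simulate the truth model under enzyme fold-change conditions and emit
    noisy measurements (Gaussian noise: additive on fluxes, on log scale for
    concentrations; ``noise_sd = 0`` gives noiseless data).

    Conditions under which the truth model fails to reach a steady state are
    dropped with a warning.
    """
    import warnings

    if bundle.truth is None:
        attach_truth(bundle)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    model = bundle.model
    flux_ids = measure_fluxes or list(model.rxn_ids)
    conc_ids = measure_concs or [model.met_ids[i] for i in model.balanced_idx]
    sd_rec = noise_sd if noise_sd > 0 else 1.0

    out: list[Condition] = []
    pred_cache: dict[tuple, object] = {}
    for k, folds in enumerate(conditions):
        cond = Condition(name=f"cond_{k}", enzyme_folds=dict(folds))
        key = tuple(sorted(folds.items()))
        if key not in pred_cache:
            pred_cache[key] = predict_condition(model, bundle.truth, cond, bundle.config)
        pred = pred_cache[key]
        if not pred.converged:
            warnings.warn(f"truth model did not converge under condition {k}; dropped")
            continue
        for rid in flux_ids:
            v = pred.fluxes[model.rxn_index[rid]] + noise_sd * rng.standard_normal()
            cond.fluxes[rid] = (float(v), sd_rec)
        for mid in conc_ids:
            c = pred.conc[model.met_index[mid]]
            c_obs = float(np.exp(np.log(c) + noise_sd * rng.standard_normal()))
            cond.concentrations[mid] = (c_obs, sd_rec)
        out.append(cond)
    bundle.observations = ObservationSet(out)
    return bundle.observations
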