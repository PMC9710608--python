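"""Sampling of one full kinetic parameterization anchored at the reference.

Given a thermodynamic state (dG, reference concentrations, resolved fluxes),
each enzyme's parameterization is drawn in four stages:

1. enzyme-state abundances at reference, flat-Dirichlet on the simplex;
2. a Gibbs partition ζ (flat-Dirichlet over the catalytic cycle steps) giving
   per-step reversibilities  r_i = exp(ζ_i·dG / RT)  whose product equals the
   overall reversibility exactly;
3. elementary rate constants back-calculated from the one-way flux
   decomposition  w⁺ = v/(1−r),  w⁻ = v·r/(1−r)  at the reference point, so
   the assembled rate reproduces the resolved flux exactly (anchoring);
4. allosteric constants (two-state MWC layer) from log-uniform priors.

Because scaled reference concentrations are all 1, anchoring and the Haldane
relationship  Π k⁺/k⁻ = exp(−dG/RT)  hold by construction for every draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mechanisms import (
    MassActionRate, MechanismError, MechanismPattern, RateFunction,
    bind_promiscuous, build_pattern, mass_action_rate,
)
from .model_io import MASS_ACTION, NetworkModel, SamplingConfig
from .thermo import R_GAS, ThermoSample


@dataclass
class AllostericParams:
    L: float                                  # T:R equilibrium with no effectors
    n_protomers: int
    K_act: dict[str, float] = field(default_factory=dict)   # scaled binding constants
    K_inh: dict[str, float] = field(default_factory=dict)


@dataclass
class EnzymeUnitParams:
    """Sampled constants for one enzyme pool (possibly promiscuous)."""
    pattern: MechanismPattern
    e_ref: np.ndarray          # reference state abundances (simplex)
    zeta: np.ndarray           # Gibbs partition per step (NaN off-cycle)
    step_r: np.ndarray         # per-step reversibility (NaN for equilibrium steps)
    k_plus: np.ndarray
    k_minus: np.ndarray

    def rate_function(self) -> RateFunction:
        return RateFunction(self.pattern, self.k_plus, self.k_minus)


@dataclass
class KineticParameterization:
    """One sampled kinetic model: all constants plus its thermodynamic state."""
    thermo: ThermoSample
    enzyme_units: dict[str, EnzymeUnitParams]
    mass_action: dict[str, MassActionRate]
    allosteric: dict[str, AllostericParams]


def build_model_patterns(model: NetworkModel) -> dict[str, MechanismPattern]:
    """Deterministic mechanism patterns per enzyme unit (merged if promiscuous)."""
    patterns: dict[str, MechanismPattern] = {}
    for eid, rxn_ids in model.enzyme_units().items():
        singles = []
        for rid in rxn_ids:
            r = model.reactions[model.rxn_index[rid]]
            singles.append(build_pattern(
                r.mechanism, rid, model.substrates(rid), model.products(rid),
                inhibitors=r.inhibitors,
            ))
        patterns[eid] = singles[0] if len(singles) == 1 else bind_promiscuous(singles)
    return patterns


# ---------------------------------------------------------------------------
# sampling stages
# ---------------------------------------------------------------------------

def sample_abundances(pattern: MechanismPattern, rng: np.random.Generator,
                      alpha: float = 1.0) -> np.ndarray:
    """Reference enzyme-state abundances, flat-Dirichlet on the open simplex."""
    n = pattern.n_states
    if n == 1:
        return np.ones(1)
    return rng.dirichlet(np.full(n, alpha))


def partition_reversibility(dG: float, pattern: MechanismPattern,
                            rng: np.random.Generator, reaction_id: str | None = None,
                            temperature: float = 298.15,
                            alpha: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Partition a reaction's Gibbs drop over its cycle steps.

    Returns per-step arrays (zeta, step_r) with NaN entries for steps outside
    the reaction's cycle.  ζ is flat-Dirichlet over the main-cycle steps;
    parallel branch paths (random-order binding) receive the same total Gibbs
    drop as the main path they shortcut, re-partitioned within the path, which
    enforces the loop (Wegscheider) condition exactly.
    """
    rid = reaction_id or pattern.reaction_ids[0]
    rt = R_GAS * temperature
    zeta = np.full(pattern.n_steps, np.nan)
    step_r = np.full(pattern.n_steps, np.nan)

    cyc = pattern.cycles[rid]
    z = rng.dirichlet(np.full(len(cyc), alpha))
    for i, frac in zip(cyc, z):
        zeta[i] = frac
        step_r[i] = math.exp(frac * dG / rt)

    for branch_point in pattern.branches.get(rid, []):
        main_path = branch_point[0]
        total = sum(zeta[i] for i in main_path)
        for alt_path in branch_point[1:]:
            sub = rng.dirichlet(np.full(len(alt_path), alpha))
            for i, frac in zip(alt_path, sub):
                zeta[i] = frac * total
                step_r[i] = math.exp(frac * total * dG / rt)
    return zeta, step_r


def _step_fluxes(pattern: MechanismPattern, reaction_id: str, v: float,
                 rng: np.random.Generator, alpha: float = 1.0) -> dict[int, float]:
    """Net flux carried by each step of a reaction's cycle at the reference.

    Steps on parallel branch paths share the net flux according to a uniform
    split on the simplex (the branch ratio is unknown, like the isoenzyme
    split); unbranched steps carry the full net flux.
    """
    flux = {i: v for i in pattern.cycles[reaction_id]}
    for branch_point in pattern.branches.get(reaction_id, []):
        frac = rng.dirichlet(np.full(len(branch_point), alpha))
        for path, f in zip(branch_point, frac):
            for i in path:
                flux[i] = v * f
    return flux


def back_calculate_constants(pattern: MechanismPattern,
                             v_resolved: Mapping[str, float],
                             e_ref: np.ndarray,
                             step_r: np.ndarray,
                             rng: np.random.Generator,
                             exchange_scale: float = 1.0,
                             exchange_range: tuple[float, float] = (0.1, 10.0),
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Back-calculate elementary rate constants from the one-way decomposition.

    For a step with net flux f and reversibility r at the reference (all scaled
    concentrations 1):  w⁺ = f/(1−r), w⁻ = w⁺·r, k⁺ = w⁺/e_src, k⁻ = w⁻/e_tgt.
    Zero-flux steps and dead-end inhibitor branches are at equilibrium and
    receive a sampled positive one-way turnover, log-uniform on
    ``exchange_range × exchange_scale``.
    """
    pos = {s: i for i, s in enumerate(pattern.states)}
    k_plus = np.zeros(pattern.n_steps)
    k_minus = np.zeros(pattern.n_steps)
    step_flux: dict[int, float] = {}
    for rid in pattern.reaction_ids:
        step_flux.update(_step_fluxes(pattern, rid, v_resolved[rid], rng))

    lo, hi = (exchange_scale * exchange_range[0], exchange_scale * exchange_range[1])

    def sample_w() -> float:
        return math.exp(rng.uniform(math.log(lo), math.log(hi)))

    for i, st in enumerate(pattern.steps):
        e_src, e_tgt = e_ref[pos[st.source]], e_ref[pos[st.target]]
        if st.is_inhibitor:
            w = sample_w()
            k_plus[i], k_minus[i] = w / e_src, w / e_tgt
            continue
        f = step_flux.get(i, 0.0)
        r = step_r[i]
        if f == 0.0 or not np.isfinite(r):
            w = sample_w()
            k_plus[i], k_minus[i] = w / e_src, w / e_tgt
            continue
        if r == 1.0:
            raise MechanismError(
                f"step {st.source}->{st.target}: reversibility 1 with nonzero flux"
            )
        w_fwd = f / (1.0 - r)
        w_rev = w_fwd * r
        if w_fwd <= 0 or w_rev < 0:
            raise MechanismError(
                f"step {st.source}->{st.target}: negative one-way flux "
                f"(f={f:g}, r={r:g}); thermodynamic state inconsistent"
            )
        k_plus[i], k_minus[i] = w_fwd / e_src, w_rev / e_tgt
    return k_plus, k_minus


def sample_allostery(reaction_regulators: tuple[Sequence[str], Sequence[str]],
                     rng: np.random.Generator,
                     config: SamplingConfig | None = None) -> AllostericParams:
    """Draw MWC-layer constants: L log-uniform, n_protomers uniform integer,
    effector binding constants log-uniform (scaled units)."""
    cfg = config or SamplingConfig()
    activators, inhibitors = reaction_regulators
    L = math.exp(rng.uniform(math.log(cfg.L_range[0]), math.log(cfg.L_range[1])))
    n = int(rng.integers(1, cfg.n_protomers_max + 1))
    klo, khi = math.log(cfg.K_eff_range[0]), math.log(cfg.K_eff_range[1])
    K_act = {m: math.exp(rng.uniform(klo, khi)) for m in activators}
    K_inh = {m: math.exp(rng.uniform(klo, khi)) for m in inhibitors}
    return AllostericParams(L=L, n_protomers=n, K_act=K_act, K_inh=K_inh)


def regulatory_factor(allo: AllostericParams,
                      activator_concs: Mapping[str, float],
                      inhibitor_concs: Mapping[str, float]) -> float:
    """Fraction of enzyme in the active (R) state under a two-state MWC model.

    factor = 1 / (1 + L_eff),
    L_eff = L·[(1 + Σ inh/K_inh) / (1 + Σ act/K_act)]^n.

    Monotone increasing in each activator, decreasing in each inhibitor; in the
    assembled model the catalytic rate is multiplied by factor/factor_ref so
    that anchoring at the reference state is preserved.
    """
    for name, c in list(activator_concs.items()) + list(inhibitor_concs.items()):
        if c < 0:
            raise ValueError(f"negative effector concentration for {name!r}")
    inh = 1.0 + sum(inhibitor_concs.get(m, 0.0) / k for m, k in allo.K_inh.items())
    act = 1.0 + sum(activator_concs.get(m, 0.0) / k for m, k in allo.K_act.items())
    L_eff = allo.L * (inh / act) ** allo.n_protomers
    return 1.0 / (1.0 + L_eff)


# ---------------------------------------------------------------------------
# full-model sampling and assembly
# ---------------------------------------------------------------------------

def sample_parameterization(model: NetworkModel,
                            patterns: Mapping[str, MechanismPattern],
                            thermo: ThermoSample,
                            config: SamplingConfig,
                            rng: np.random.Generator) -> KineticParameterization:
    """Draw one complete kinetic parameterization anchored at ``thermo``."""
    nz = np.abs(thermo.v_resolved[thermo.v_resolved != 0])
    flux_scale = float(np.median(nz)) if nz.size else 1.0

    units: dict[str, EnzymeUnitParams] = {}
    for eid, pattern in patterns.items():
        e_ref = sample_abundances(pattern, rng, config.dirichlet_alpha)
        zeta = np.full(pattern.n_steps, np.nan)
        step_r = np.full(pattern.n_steps, np.nan)
        v_map: dict[str, float] = {}
        for rid in pattern.reaction_ids:
            j = model.rxn_index[rid]
            v_map[rid] = float(thermo.v_resolved[j])
            if v_map[rid] != 0.0:
                z, r = partition_reversibility(
                    float(thermo.dG[j]), pattern, rng, reaction_id=rid,
                    temperature=thermo.temperature, alpha=config.dirichlet_alpha)
                mask = ~np.isnan(z)
                zeta[mask], step_r[mask] = z[mask], r[mask]
        k_plus, k_minus = back_calculate_constants(
            pattern, v_map, e_ref, step_r, rng,
            exchange_scale=flux_scale, exchange_range=config.exchange_flux_range)
        units[eid] = EnzymeUnitParams(pattern, e_ref, zeta, step_r, k_plus, k_minus)

    ma: dict[str, MassActionRate] = {}
    allo: dict[str, AllostericParams] = {}
    for j, rxn in enumerate(model.reactions):
        if rxn.mechanism == MASS_ACTION:
            v = float(thermo.v_resolved[j])
            r_ref = float(np.exp(thermo.dG[j] / (R_GAS * thermo.temperature)))
            k_eq = None
            if v == 0.0:
                lo, hi = config.exchange_flux_range
                k_eq = flux_scale * math.exp(rng.uniform(math.log(lo), math.log(hi)))
            ma[rxn.id] = mass_action_rate(
                rxn.id, model.substrates(rxn.id), model.products(rxn.id), v, r_ref,
                k_equilibrium=k_eq)
        if rxn.allosteric:
            allo[rxn.id] = sample_allostery((rxn.activators, rxn.neg_effectors),
                                            rng, config)
    return KineticParameterization(thermo=thermo, enzyme_units=units,
                                   mass_action=ma, allosteric=allo)


class ModelRates:
    """Net rates of the whole network as a function of scaled concentrations.

    ``conc`` maps every metabolite id to its scaled concentration (1 at the
    reference); ``enzyme_folds`` maps enzyme ids (see
    :meth:`NetworkModel.enzyme_id`) and/or mass-action reaction ids to scaled
    enzyme levels.  Returns the flux vector in network reaction order.
    Allosteric reactions are modulated by the MWC factor normalized to its
    reference value, so anchoring survives regulation.
    """

    def __init__(self, model: NetworkModel, params: KineticParameterization):
        self.model = model
        self.params = params
        self._rate_fns = {eid: u.rate_function()
                          for eid, u in params.enzyme_units.items()}
        self._factor_ref: dict[str, float] = {}
        ref_conc = {m: 1.0 for m in model.met_ids}
        for rid, a in params.allosteric.items():
            rxn = model.reactions[model.rxn_index[rid]]
            self._factor_ref[rid] = regulatory_factor(
                a, {m: ref_conc[m] for m in rxn.activators},
                {m: ref_conc[m] for m in rxn.neg_effectors})

    def __call__(self, conc: Mapping[str, float],
                 enzyme_folds: Mapping[str, float] | None = None) -> np.ndarray:
        folds = enzyme_folds or {}
        v = np.zeros(self.model.n_reactions)
        for eid, fn in self._rate_fns.items():
            rates = fn(conc, e_total=folds.get(eid, 1.0))
            for rid, val in rates.items():
                v[self.model.rxn_index[rid]] = val
        for rid, fn in self.params.mass_action.items():
            v[self.model.rxn_index[rid]] = fn(conc, e_total=folds.get(rid, 1.0))[rid]
        for rid, a in self.params.allosteric.items():
            rxn = self.model.reactions[self.model.rxn_index[rid]]
            f = regulatory_factor(a, {m: conc[m] for m in rxn.activators},
                                  {m: conc[m] for m in rxn.neg_effectors})
            v[self.model.rxn_index[rid]] *= f / self._factor_ref[rid]
        return v

    def reference_rates(self) -> np.ndarray:
        return self({m: 1.0 for m in self.model.met_ids})
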