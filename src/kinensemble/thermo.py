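"""Thermodynamic feasibility and sampling of consistent thermodynamic states.

The central quantity is the Gibbs energy of reaction *at the reference state*
(concentration-included).  Feasibility means: for every flux-carrying reaction
sign(dG) = -sign(v), and around every internal stoichiometric loop the Gibbs
energies sum to zero (first law).  Both are enforced as hard constraints —
first by LP tightening of the input ranges, then during sampling.

The dimensionless reversibility r = exp(dG / (R·T)) is the ratio of reverse to
forward one-way flux through a reaction at the sampled state and is the single
thermodynamic anchor used by the kinetic parameterization downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model_io import NetworkModel, ReferenceState

R_GAS = 8.314e-3   # kJ / (mol K)

#: margin (kJ/mol) keeping tightened ranges strictly on the required side of 0
SIGN_MARGIN = 1e-6


class ThermodynamicInfeasibilityError(ValueError):
    pass


@dataclass
class ThermoSample:
    """One sampled thermodynamic state of the network."""
    dG: np.ndarray          # (n_rxn,) kJ/mol at the reference state
    conc_ref: np.ndarray    # (n_met,) mol/L, sampled reference concentrations
    v_resolved: np.ndarray  # (n_rxn,) net fluxes with isoenzyme groups split
    temperature: float = 298.15

    @property
    def reversibilities(self) -> np.ndarray:
        return reversibility(self.dG, self.temperature)


def reversibility(dG, T: float = 298.15):
    """r = exp(dG / (R·T)); r < 1 iff dG < 0 (forward-favoured)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return np.exp(np.asarray(dG, dtype=float) / (R_GAS * T))


def _loop_basis(model: NetworkModel, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of internal flux loops, columns = loops.

    Built over *all* declared metabolites so that exchange reactions touching
    declared boundary species do not form spurious loops; one-sided columns
    (pure sources/sinks, whose external counterpart species is implicit) are
    excluded outright — a source + sink pathway is not a thermodynamic cycle.
    """
    S = model.stoichiometry
    n_r = model.n_reactions
    if S.size == 0:
        return np.zeros((n_r, 0))
    internal = [j for j in range(n_r)
                if (S[:, j] < 0).any() and (S[:, j] > 0).any()]
    if not internal:
        return np.zeros((n_r, 0))
    Si = S[:, internal]
    _, s, vt = np.linalg.svd(Si)
    rank = int((s > tol * (s[0] if s.size else 1.0)).sum())
    loops_int = vt[rank:].T
    loops = np.zeros((n_r, loops_int.shape[1]))
    loops[internal, :] = loops_int
    return loops


def _sign_bounds(v: np.ndarray, dG_range: np.ndarray) -> np.ndarray:
    """Intersect dG ranges with the flux-direction half-lines."""
    out = dG_range.astype(float).copy()
    for j, vj in enumerate(v):
        if vj > 0:
            out[j, 1] = min(out[j, 1], -SIGN_MARGIN)
        elif vj < 0:
            out[j, 0] = max(out[j, 0], SIGN_MARGIN)
    return out


def tighten_dg_bounds(model: NetworkModel, ref: ReferenceState) -> ReferenceState:
    """Tighten dG ranges by LP over the joint feasibility polytope.

    The polytope is {dG : dG within ranges, sign(dG_j) = -sign(v_j) for
    flux-carrying j, and λᵀ·dG = 0 for every internal loop λ}.  Each bound is
    replaced by the LP extreme of dG_j over that polytope, so tightened ranges
    are non-empty subsets of the originals and the operation is idempotent.

    Raises :class:`ThermodynamicInfeasibilityError` naming the first reaction
    whose range excludes the flux-required sign (or, with loops, the reaction
    whose bound collapses).
    """
    out = ref.copy()
    v = ref.nominal_flux(model)
    bounds = _sign_bounds(v, ref.dG_range)

    for j, rid in enumerate(model.rxn_ids):
        if bounds[j, 0] > bounds[j, 1]:
            raise ThermodynamicInfeasibilityError(
                f"reaction {rid!r}: dG range {list(ref.dG_range[j])} excludes the sign "
                f"required by v_ref = {v[j]:g}"
            )

    loops = _loop_basis(model)
    if loops.shape[1] == 0:
        out.dG_range = bounds
        return out

    n = model.n_reactions
    A_eq = loops.T
    b_eq = np.zeros(A_eq.shape[0])
    lp_bounds = [tuple(bounds[j]) for j in range(n)]
    tightened = bounds.copy()
    for j in range(n):
        for sense, col in ((1.0, 0), (-1.0, 1)):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=lp_bounds, method="highs")
            if not res.success:
                raise ThermodynamicInfeasibilityError(
                    f"no thermodynamically feasible state: bound for reaction "
                    f"{model.rxn_ids[j]!r} is infeasible under loop constraints"
                )
            tightened[j, col] = sense * res.fun
    # numerical guard: stay inside the sign-constrained box
    tightened[:, 0] = np.maximum(tightened[:, 0], bounds[:, 0])
    tightened[:, 1] = np.minimum(tightened[:, 1], bounds[:, 1])
    out.dG_range = tightened
    return out


def _split_iso_fluxes(model: NetworkModel, ref: ReferenceState,
                      rng: np.random.Generator) -> np.ndarray:
    """Resolve isoenzyme group fluxes with a flat-simplex split of the group flux."""
    v = ref.v_ref.copy()
    for gid, members in model.isoenzyme_groups().items():
        total = ref.group_flux[gid]
        frac = rng.dirichlet(np.ones(len(members)))
        for rid, f in zip(members, frac):
            v[model.rxn_index[rid]] = total * f
    return v


def sample_thermo_state(model: NetworkModel, ref_tightened: ReferenceState,
                        rng: np.random.Generator,
                        max_tries: int = 10000) -> ThermoSample:
    """Draw one feasible thermodynamic state.

    Reference concentrations are sampled log-uniformly within their ranges.
    Gibbs energies are sampled uniformly within the tightened ranges; if the
    network contains internal loops the box draw is projected orthogonally onto
    the loop-law subspace and accepted only if it still satisfies all box and
    sign constraints (exactly uniform for loop-free networks).  Isoenzyme group
    fluxes are split uniformly on the simplex, preserving the group sign.
    """
    bounds = _sign_bounds(ref_tightened.nominal_flux(model), ref_tightened.dG_range)
    if (bounds[:, 0] > bounds[:, 1]).any():
        j = int(np.nonzero(bounds[:, 0] > bounds[:, 1])[0][0])
        raise ThermodynamicInfeasibilityError(
            f"reaction {model.rxn_ids[j]!r} has an empty feasible dG range; "
            f"run tighten_dg_bounds first"
        )

    log_lo = np.log(ref_tightened.conc_range[:, 0])
    log_hi = np.log(ref_tightened.conc_range[:, 1])
    conc_ref = np.exp(rng.uniform(log_lo, log_hi))

    v_resolved = _split_iso_fluxes(model, ref_tightened, rng)

    loops = _loop_basis(model)
    proj = None
    if loops.shape[1]:
        proj = np.eye(model.n_reactions) - loops @ loops.T

    for _ in range(max_tries):
        g = rng.uniform(bounds[:, 0], bounds[:, 1])
        if proj is not None:
            g = proj @ g
            inside = (g >= bounds[:, 0] - 1e-12) & (g <= bounds[:, 1] + 1e-12)
            if not inside.all():
                continue
            g = np.clip(g, bounds[:, 0], bounds[:, 1])
        return ThermoSample(dG=g, conc_ref=conc_ref, v_resolved=v_resolved,
                            temperature=ref_tightened.temperature)

    widths = bounds[:, 1] - bounds[:, 0]
    tight = [model.rxn_ids[j] for j in np.argsort(widths)[:3]]
    raise ThermodynamicInfeasibilityError(
        f"no feasible dG draw in {max_tries} tries; tightest ranges at reactions {tight} "
        f"(the feasible region may have near-zero measure)"
    )
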