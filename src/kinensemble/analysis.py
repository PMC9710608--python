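"""Metabolic control analysis and dynamic simulation.

All computations run in scaled space: metabolite concentrations relative to the
sampled reference concentrations, enzyme levels relative to the reference.
The reference state (all scaled inputs = 1) is a fixed point of the dynamics
by construction of the anchored parameterization.

Conserved moieties (e.g. an ATP+ADP pool) make the stoichiometric matrix row
rank-deficient; they are handled with the standard link-matrix decomposition
S = L·N_r, integrating only an independent subset of metabolites and
reconstructing the rest, and the reduced Jacobian is used for control
coefficients:

    C^S = −(N̂_r·(∂v/∂x)·L̂)⁻¹·N̂_r·diag(v),   C^J = I + ε·L̂·C^S

which yields the classical summation theorems (flux-control rows sum to 1,
concentration-control rows to 0) and connectivity identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_io import NetworkModel, SamplingConfig
from .param_sampling import KineticParameterization, ModelRates


class SingularJacobianError(ArithmeticError):
    pass


# ---------------------------------------------------------------------------
# conserved moieties
# ---------------------------------------------------------------------------

def conserved_moieties(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Link-matrix decomposition S = L_link · N_r (exact, rational arithmetic).

    Returns (L_link, N_r, pivots): N_r are the independent rows of S (full row
    rank), L_link reconstructs all rows, and ``pivots`` are the indices of the
    independent metabolites.  For a matrix of full row rank, L_link is the
    identity (no conserved moieties).
    """
    S = np.asarray(S, dtype=float)
    n_m = S.shape[0]
    if n_m == 0:
        return np.zeros((0, 0)), S.copy(), []
    M = sympy.Matrix(sympy.nsimplify(sympy.Matrix(S), rational=True))
    rref_T, piv = M.T.rref()
    pivots = [int(p) for p in piv]
    # row i of S = sum_k rref_T[k, i] * row pivots[k] of S
    L = np.zeros((n_m, len(pivots)))
    for i in range(n_m):
        for k in range(len(pivots)):
            L[i, k] = float(rref_T[k, i])
    N_r = S[pivots, :]
    return L, N_r, pivots


# ---------------------------------------------------------------------------
# elasticities
# ---------------------------------------------------------------------------

FD_LOG_STEP = 1e-6


def rate_jacobian(model: NetworkModel, rates: ModelRates,
                  enzyme_folds: dict[str, float] | None = None,
                  x0: dict[str, float] | None = None) -> np.ndarray:
    """∂v/∂ln x over balanced metabolites by central differences in log space.

    At the reference point (x = 1) this equals the unscaled Jacobian ∂v/∂x̂.
    """
    base = x0 or {m: 1.0 for m in model.met_ids}
    cols = []
    for i in model.balanced_idx:
        mid = model.met_ids[i]
        up, dn = dict(base), dict(base)
        up[mid] = base[mid] * np.exp(FD_LOG_STEP)
        dn[mid] = base[mid] * np.exp(-FD_LOG_STEP)
        cols.append((rates(up, enzyme_folds) - rates(dn, enzyme_folds)) / (2 * FD_LOG_STEP))
    return np.column_stack(cols) if cols else np.zeros((model.n_reactions, 0))


def elasticity_matrix(model: NetworkModel, params: KineticParameterization,
                      rates: ModelRates | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Scaled elasticities ε_ij = ∂ln v_i / ∂ln x_j at the reference point.

    Returns (epsilon, zero_flux_mask).  Rows of zero-flux reactions hold the
    *unscaled* derivative ∂v/∂ln x (the log-derivative is undefined at v = 0)
    and are flagged in the mask.
    """
    rates = rates or ModelRates(model, params)
    J = rate_jacobian(model, rates)
    v = params.thermo.v_resolved
    eps = J.copy()
    zero = v == 0.0
    nz = ~zero
    eps[nz, :] = J[nz, :] / v[nz, None]
    return eps, zero


def mass_action_elasticities(model: NetworkModel, params: KineticParameterization,
                             rxn_id: str) -> np.ndarray:
    """Analytic elasticities of a mass-action reaction at the reference point.

    v = k(Π s^a − r Π p^b) gives ε_s = a·k/v and ε_p = −b·k·r/v at scaled
    concentrations 1 (power-law limbs).  Used to cross-check the finite
    differences; mechanistic rates have no closed form after the
    pseudo-steady-state reduction and always use finite differences.
    """
    fn = params.mass_action[rxn_id]
    j = model.rxn_index[rxn_id]
    v = params.thermo.v_resolved[j]
    eps = np.zeros(len(model.balanced_idx))
    bpos = {model.met_ids[i]: b for b, i in enumerate(model.balanced_idx)}
    if v == 0.0:
        for m, c in fn.substrates:
            if m in bpos:
                eps[bpos[m]] += c * fn.k
        for m, c in fn.products:
            if m in bpos:
                eps[bpos[m]] -= c * fn.k * fn.r_ref
        return eps
    for m, c in fn.substrates:
        if m in bpos:
            eps[bpos[m]] += c * fn.k / v
    if not fn.one_sided:
        for m, c in fn.products:
            if m in bpos:
                eps[bpos[m]] -= c * fn.k * fn.r_ref / v
    return eps


# ---------------------------------------------------------------------------
# control coefficients
# ---------------------------------------------------------------------------

@dataclass
class ControlCoefficients:
    epsilon: np.ndarray          # reactions x balanced metabolites (scaled)
    zero_flux: np.ndarray        # mask of reactions where epsilon is unscaled
    CJ: np.ndarray               # flux control, reactions x reactions
    CS: np.ndarray               # concentration control, balanced mets x reactions
    CS_ind: np.ndarray           # independent-metabolite block used internally
    L_link: np.ndarray
    N_r: np.ndarray
    pivots: list[int]
    condition_number: float


def control_coefficients(model: NetworkModel, params: KineticParameterization,
                         rates: ModelRates | None = None,
                         cond_threshold: float = 1e12) -> ControlCoefficients:
    """Flux and concentration control coefficients at the reference steady state.

    Control is defined with respect to enzyme-activity perturbations: each
    reaction's activity scales its rate linearly, so ∂v_i/∂ln a_j = v_i·δ_ij.
    """
    rates = rates or ModelRates(model, params)
    v = params.thermo.v_resolved
    J = rate_jacobian(model, rates)                    # ∂v/∂x̂ at reference
    eps, zero = elasticity_matrix(model, params, rates)

    L, N_r, piv = conserved_moieties(model.S)
    c_ref_b = params.thermo.conc_ref[model.balanced_idx]
    # scaled-space link and reduced stoichiometry: x̂ = D⁻¹c
    L_hat = (L * c_ref_b[piv][None, :]) / c_ref_b[:, None]
    N_hat = model.S[piv, :] / c_ref_b[piv][:, None]

    M = N_hat @ J @ L_hat
    cond = float(np.linalg.cond(M)) if M.size else 0.0
    if M.size and cond > cond_threshold:
        w, V = np.linalg.eig(M)
        k = int(np.argmin(np.abs(w)))
        mode_met = model.met_ids[model.balanced_idx[piv[int(np.argmax(np.abs(V[:, k])))]]]
        raise SingularJacobianError(
            f"reduced Jacobian is singular/ill-conditioned (cond = {cond:.3g}); "
            f"near-zero mode dominated by metabolite {mode_met!r}"
        )

    CS_ind = -np.linalg.solve(M, N_hat @ np.diag(v)) if M.size else np.zeros((0, len(v)))
    CS = L_hat @ CS_ind
    n = model.n_reactions
    CJ = np.eye(n)
    resp = J @ L_hat @ CS_ind                          # dv/dln a (indirect part)
    nzr = v != 0.0
    CJ[nzr, :] += resp[nzr, :] / v[nzr, None]
    CJ[~nzr, :] = np.nan                               # undefined for zero-flux rows
    return ControlCoefficients(eps, zero, CJ, CS, CS_ind, L, N_r, piv, cond)


# ---------------------------------------------------------------------------
# dynamic simulation
# ---------------------------------------------------------------------------

@dataclass
class Perturbation:
    enzyme_folds: dict[str, float] = field(default_factory=dict)
    conc_overrides: dict[str, float] = field(default_factory=dict)  # scaled initial values


@dataclass
class Trajectory:
    t: np.ndarray                # time grid
    conc: np.ndarray             # n_t x n_metabolites (scaled, all declared mets)
    rates: np.ndarray            # n_t x n_reactions
    converged: bool
    residual: float              # ||dx/dt||_inf / max(||x||_inf, 1) at the end
    met_ids: list[str]
    rxn_ids: list[str]


def simulate_timecourse(model: NetworkModel, params: KineticParameterization,
                        perturbation: Perturbation | None = None,
                        t_end: float = 1000.0,
                        config: SamplingConfig | None = None,
                        n_points: int = 100,
                        polish: bool = False) -> Trajectory:
    """Integrate the perturbed network from the reference initial point.

    The ODE runs on the independent scaled concentrations (conserved moieties
    reconstructed through the link matrix); integration is stiff-capable
    (LSODA).  With ``polish`` the final state is refined by a Newton solve of
    the steady-state condition.
    """
    cfg = config or SamplingConfig()
    pert = perturbation or Perturbation()
    rates = ModelRates(model, params)
    folds = dict(pert.enzyme_folds)

    L, _, piv = conserved_moieties(model.S)
    c_ref_b = params.thermo.conc_ref[model.balanced_idx]
    L_hat = (L * c_ref_b[piv][None, :]) / c_ref_b[:, None]
    N_hat = model.S[piv, :] / c_ref_b[piv][:, None]

    x_full0 = np.ones(model.n_metabolites)
    for m, val in pert.conc_overrides.items():
        x_full0[model.met_index[m]] = val
    xb0 = x_full0[model.balanced_idx]
    xi0 = xb0[piv]

    def full_conc(xi: np.ndarray) -> dict[str, float]:
        xb = xb0 + L_hat @ (xi - xi0)
        conc = {m: x_full0[model.met_index[m]] for m in model.met_ids}
        for b, i in enumerate(model.balanced_idx):
            conc[model.met_ids[i]] = xb[b]
        return conc

    def rhs(_t, xi):
        return N_hat @ rates(full_conc(xi), folds)

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), xi0, method="LSODA",
                    rtol=cfg.ode_rtol, atol=cfg.ode_atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed at t = {sol.t[-1] if sol.t.size else 0:g}: "
                           f"{sol.message}")

    xi_end = sol.y[:, -1]
    if polish:
        res = root(lambda z: rhs(0.0, z), xi_end, method="hybr", tol=1e-12)
        if res.success and np.all(np.isfinite(res.x)):
            xi_end = res.x
            sol.y[:, -1] = xi_end

    n_t = sol.t.size
    conc = np.zeros((n_t, model.n_metabolites))
    vmat = np.zeros((n_t, model.n_reactions))
    for k in range(n_t):
        cmap = full_conc(sol.y[:, k])
        conc[k] = [cmap[m] for m in model.met_ids]
        vmat[k] = rates(cmap, folds)

    dxi = rhs(0.0, xi_end)
    denom = max(float(np.abs(xi_end).max()) if xi_end.size else 1.0, 1.0)
    residual = float(np.abs(dxi).max() / denom) if dxi.size else 0.0
    return Trajectory(t=sol.t, conc=conc, rates=vmat,
                      converged=residual < cfg.ss_tol, residual=residual,
                      met_ids=list(model.met_ids), rxn_ids=list(model.rxn_ids))


def steady_state(model: NetworkModel, params: KineticParameterization,
                 perturbation: Perturbation | None = None,
                 config: SamplingConfig | None = None,
                 t_end: float | None = None) -> Trajectory:
    """Simulate to steady state with a Newton polish of the endpoint."""
    cfg = config or SamplingConfig()
    return simulate_timecourse(model, params, perturbation,
                               t_end=t_end if t_end is not None else cfg.t_end,
                               config=cfg, n_points=20, polish=True)


def moiety_totals(model: NetworkModel, traj: Trajectory,
                  conc_ref: np.ndarray) -> np.ndarray:
    """Conserved-moiety totals along a trajectory (rows = time, cols = moieties).

    Computed from a rational basis of the left null space of S in unscaled
    concentration units; constant along any exact solution.
    """
    M = sympy.Matrix(sympy.nsimplify(sympy.Matrix(model.S), rational=True))
    null_T = M.T.nullspace()
    if not null_T:
        return np.zeros((traj.t.size, 0))
    basis = np.column_stack([np.array(vec, dtype=float).ravel() for vec in null_T])
    c_unscaled = traj.conc[:, model.balanced_idx] * conc_ref[model.balanced_idx][None, :]
    return c_unscaled @ basis


# ---------------------------------------------------------------------------
# ensemble aggregation
# ---------------------------------------------------------------------------

def ensemble_mca(model: NetworkModel, parameterizations,
                 quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)):
    """Per-cell quantiles of control coefficients across an ensemble.

    Returns (flux_df, conc_df, n_excluded): long-format tables with one row per
    (controller reaction, target) pair; models whose Jacobian is singular are
    excluded and counted.
    """
    import pandas as pd

    cj_list, cs_list, excluded = [], [], 0
    for p in parameterizations:
        try:
            cc = control_coefficients(model, p)
        except (SingularJacobianError, np.linalg.LinAlgError):
            excluded += 1
            continue
        cj_list.append(cc.CJ)
        cs_list.append(cc.CS)
    if not cj_list:
        raise ValueError("no model produced valid control coefficients")

    qlabels = [f"q{int(100 * q):02d}" for q in quantiles]

    def table(stack, targets):
        arr = np.stack(stack)                 # models x targets x controllers
        rows = []
        for ti, target in enumerate(targets):
            for cj, controller in enumerate(model.rxn_ids):
                vals = arr[:, ti, cj]
                vals = vals[np.isfinite(vals)]
                rec = {"target": target, "controller": controller,
                       "mean": float(vals.mean()) if vals.size else np.nan}
                for q, lab in zip(quantiles, qlabels):
                    rec[lab] = float(np.quantile(vals, q)) if vals.size else np.nan
                rows.append(rec)
        return pd.DataFrame(rows)

    balanced_mets = [model.met_ids[i] for i in model.balanced_idx]
    return table(cj_list, model.rxn_ids), table(cs_list, balanced_mets), excluded
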