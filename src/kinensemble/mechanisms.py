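"""Catalytic mechanisms as elementary-step patterns, and their rate functions.

A mechanistic reaction is decomposed into elementary transitions between enzyme
intermediates, each governed by mass action.  The built-in library covers the
classic single-enzyme mechanisms:

``uniUni``       E + S <=> ES <=> EP <=> E + P                  (3 steps)
``orderedBiBi``  E + A <=> EA; EA + B <=> EAB <=> EPQ;
                 EPQ <=> EQ + P; EQ <=> E + Q                   (5 steps)
``randomBiBi``   as orderedBiBi but A and B bind in either order (branched)
``pingPong``     E + A <=> EA <=> F + P; F + B <=> FB <=> E + Q (4 steps)

plus user-defined linear cycles from a step-list table.  Competitive inhibitors
are appended as dead-end branches on the free enzyme; promiscuous enzymes share
one free-enzyme state across several catalytic cycles.

State naming is canonical — free enzyme ``E``, intermediates ``<rxn>.<tag>``
(tags ES, EP, EA, EAB, EPQ, EQ, F, FB), inhibitor complexes ``EI.<metabolite>``
— so that a fixed seed reproduces identical parameter vectors across runs.

Rates are evaluated in scaled space: metabolite concentrations and total enzyme
are expressed relative to the reference state, where every scaled input is 1.
By default, enzyme-intermediate abundances are resolved by the pseudo-steady-
state solution of the linear intermediate balance at the given metabolite
concentrations, so the dynamic system lives in metabolite space only; an
explicit-intermediates mode (`state_derivatives`) exists for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

FREE_ENZYME = "E"


class MechanismError(ValueError):
    pass


@dataclass(frozen=True)
class Step:
    """One elementary transition source -> target.

    ``substrates`` are bound (consumed) in the forward direction, ``products``
    released.  Dead-end inhibitor-binding steps carry no catalytic flux.
    """
    source: str
    target: str
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    reaction: str | None = None
    is_inhibitor: bool = False


@dataclass
class MechanismPattern:
    reaction_ids: list[str]
    states: list[str]
    steps: list[Step]
    #: per reaction: indices of the main catalytic cycle (a spanning path E -> ... -> E)
    cycles: dict[str, list[int]]
    #: per reaction: index of the step whose net rate *is* the reaction rate
    flux_step: dict[str, int]
    #: per reaction: branch points [(alternative paths as step-index lists)]
    branches: dict[str, list[list[list[int]]]] = field(default_factory=dict)
    kind: str = "linear"

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def state_pos(self, name: str) -> int:
        return self.states.index(name)

    def validate(self) -> None:
        pos = {s: i for i, s in enumerate(self.states)}
        if self.states[0] != FREE_ENZYME:
            raise MechanismError("free enzyme must be the first state")
        for st in self.steps:
            if st.source not in pos or st.target not in pos:
                raise MechanismError(f"step {st} references unknown state")
        for rid, cyc in self.cycles.items():
            if self.steps[cyc[0]].source != FREE_ENZYME or self.steps[cyc[-1]].target != FREE_ENZYME:
                raise MechanismError(f"cycle of {rid!r} does not return to the free enzyme")
            for a, b in zip(cyc, cyc[1:]):
                if self.steps[a].target != self.steps[b].source:
                    raise MechanismError(f"cycle of {rid!r} is not a connected path")
        for st in self.steps:
            if st.is_inhibitor:
                # dead end: nothing may leave the inhibitor complex except back
                outgoing = [o for o in self.steps
                            if not o.is_inhibitor and o.source == st.target]
                if outgoing:
                    raise MechanismError(f"inhibitor state {st.target!r} is not a dead end")


# ---------------------------------------------------------------------------
# pattern library
# ---------------------------------------------------------------------------

def _unit_stoich(pairs: Sequence[tuple[str, float]], n: int, rxn: str, side: str) -> list[str]:
    if len(pairs) != n or any(abs(c - 1.0) > 1e-12 for _, c in pairs):
        raise MechanismError(
            f"reaction {rxn!r}: mechanism requires {n} {side}(s) with unit stoichiometry, "
            f"got {pairs}"
        )
    return [m for m, _ in pairs]


def build_pattern(mechanism: str, reaction_id: str,
                  substrates: Sequence[tuple[str, float]],
                  products: Sequence[tuple[str, float]],
                  inhibitors: Sequence[str] = ()) -> MechanismPattern:
    """Build a built-in mechanism pattern for one reaction.

    ``substrates``/``products`` are (metabolite, stoichiometric coefficient)
    pairs taken from the network column; the mechanism arity must match.
    """
    rid = reaction_id
    t = lambda tag: f"{rid}.{tag}"

    if mechanism == "uniUni":
        (s,) = _unit_stoich(substrates, 1, rid, "substrate")
        (p,) = _unit_stoich(products, 1, rid, "product")
        states = [FREE_ENZYME, t("ES"), t("EP")]
        steps = [
            Step(FREE_ENZYME, t("ES"), (s,), (), rid),
            Step(t("ES"), t("EP"), (), (), rid),
            Step(t("EP"), FREE_ENZYME, (), (p,), rid),
        ]
        cycles = {rid: [0, 1, 2]}
        branches = {}
        kind = "linear"
    elif mechanism == "orderedBiBi":
        a, b = _unit_stoich(substrates, 2, rid, "substrate")
        p, q = _unit_stoich(products, 2, rid, "product")
        states = [FREE_ENZYME, t("EA"), t("EAB"), t("EPQ"), t("EQ")]
        steps = [
            Step(FREE_ENZYME, t("EA"), (a,), (), rid),
            Step(t("EA"), t("EAB"), (b,), (), rid),
            Step(t("EAB"), t("EPQ"), (), (), rid),
            Step(t("EPQ"), t("EQ"), (), (p,), rid),
            Step(t("EQ"), FREE_ENZYME, (), (q,), rid),
        ]
        cycles = {rid: [0, 1, 2, 3, 4]}
        branches = {}
        kind = "linear"
    elif mechanism == "randomBiBi":
        a, b = _unit_stoich(substrates, 2, rid, "substrate")
        p, q = _unit_stoich(products, 2, rid, "product")
        states = [FREE_ENZYME, t("EA"), t("EB"), t("EAB"), t("EPQ"), t("EQ")]
        steps = [
            Step(FREE_ENZYME, t("EA"), (a,), (), rid),   # 0  main branch
            Step(t("EA"), t("EAB"), (b,), (), rid),      # 1
            Step(FREE_ENZYME, t("EB"), (b,), (), rid),   # 2  alt branch
            Step(t("EB"), t("EAB"), (a,), (), rid),      # 3
            Step(t("EAB"), t("EPQ"), (), (), rid),       # 4
            Step(t("EPQ"), t("EQ"), (), (p,), rid),      # 5
            Step(t("EQ"), FREE_ENZYME, (), (q,), rid),   # 6
        ]
        cycles = {rid: [0, 1, 4, 5, 6]}
        branches = {rid: [[[0, 1], [2, 3]]]}
        kind = "branched"
    elif mechanism == "pingPong":
        a, b = _unit_stoich(substrates, 2, rid, "substrate")
        p, q = _unit_stoich(products, 2, rid, "product")
        states = [FREE_ENZYME, t("EA"), t("F"), t("FB")]
        steps = [
            Step(FREE_ENZYME, t("EA"), (a,), (), rid),
            Step(t("EA"), t("F"), (), (p,), rid),
            Step(t("F"), t("FB"), (b,), (), rid),
            Step(t("FB"), FREE_ENZYME, (), (q,), rid),
        ]
        cycles = {rid: [0, 1, 2, 3]}
        branches = {}
        kind = "linear"
    else:
        raise MechanismError(f"unknown mechanism {mechanism!r} for reaction {rid!r}")

    pat = MechanismPattern([rid], states, steps, cycles,
                           flux_step={rid: cycles[rid][-1]},
                           branches=branches, kind=kind)
    for inh in inhibitors:
        _append_inhibitor(pat, rid, inh)
    pat.validate()
    return pat


def pattern_from_steps(reaction_id: str,
                       rows: Sequence[tuple[str, str, str, str]],
                       inhibitors: Sequence[str] = ()) -> MechanismPattern:
    """User-defined linear cycle from (source, target, metabolite, role) rows.

    ``role`` is ``substrate``, ``product`` or empty; states must form a single
    path starting and ending at the free enzyme ``E``.
    """
    steps: list[Step] = []
    states: list[str] = [FREE_ENZYME]
    for src, tgt, met, role in rows:
        subs = (met,) if role == "substrate" and met else ()
        prods = (met,) if role == "product" and met else ()
        if role not in ("substrate", "product", "", "none"):
            raise MechanismError(f"unknown step role {role!r}")
        steps.append(Step(src, tgt, subs, prods, reaction_id))
        for s in (src, tgt):
            if s not in states:
                states.append(s)
    pat = MechanismPattern([reaction_id], states, steps,
                           cycles={reaction_id: list(range(len(steps)))},
                           flux_step={reaction_id: len(steps) - 1},
                           kind="linear")
    for inh in inhibitors:
        _append_inhibitor(pat, reaction_id, inh)
    pat.validate()
    return pat


def _append_inhibitor(pat: MechanismPattern, rid: str, metabolite: str) -> None:
    state = f"EI.{metabolite}"
    if state not in pat.states:
        pat.states.append(state)
    pat.steps.append(Step(FREE_ENZYME, state, (metabolite,), (), rid, is_inhibitor=True))


def bind_promiscuous(patterns: Sequence[MechanismPattern]) -> MechanismPattern:
    """Merge single-reaction patterns into one enzyme sharing the free state.

    The merged state space keeps one ``E``; each reaction keeps its own
    catalytic branch, and total enzyme conservation spans all branches, which
    couples the branch rates (saturating one substrate drains enzyme from the
    other branches).
    """
    states = [FREE_ENZYME]
    steps: list[Step] = []
    cycles: dict[str, list[int]] = {}
    flux_step: dict[str, int] = {}
    branches: dict[str, list[list[list[int]]]] = {}
    rids: list[str] = []
    for pat in patterns:
        offset = len(steps)
        remap = {i: i + offset for i in range(pat.n_steps)}
        for s in pat.states:
            if s not in states:
                states.append(s)
        for st in pat.steps:
            steps.append(st)
        for rid in pat.reaction_ids:
            rids.append(rid)
            cycles[rid] = [remap[i] for i in pat.cycles[rid]]
            flux_step[rid] = remap[pat.flux_step[rid]]
            if rid in pat.branches:
                branches[rid] = [[[remap[i] for i in path] for path in bp]
                                 for bp in pat.branches[rid]]
    merged = MechanismPattern(rids, states, steps, cycles, flux_step, branches,
                              kind="promiscuous")
    merged.validate()
    return merged


def enumerate_states(pattern: MechanismPattern) -> list[str]:
    """Ordered enzyme states; abundances are normalized to Σ e_i = 1 (scaled
    total enzyme) at the reference."""
    return list(pattern.states)


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

class RateFunction:
    """Evaluatable net-rate mapping for one enzyme unit (pattern + constants).

    Calling it with scaled metabolite concentrations (mapping id -> value) and
    a scaled total-enzyme level returns {reaction id: net rate} in flux units.
    Enzyme intermediates are resolved by the pseudo-steady-state solution of
    the linear balance  A(c)·e = 0, Σe = e_total;  the reaction net rate is
    the net flow through its product-release step.
    """

    def __init__(self, pattern: MechanismPattern,
                 k_plus: np.ndarray, k_minus: np.ndarray):
        if len(k_plus) != pattern.n_steps or len(k_minus) != pattern.n_steps:
            raise MechanismError("one (k_plus, k_minus) pair per elementary step required")
        self.pattern = pattern
        self.k_plus = np.asarray(k_plus, dtype=float)
        self.k_minus = np.asarray(k_minus, dtype=float)
        self._pos = {s: i for i, s in enumerate(pattern.states)}

    # -- internals ----------------------------------------------------------

    def _step_coeffs(self, conc: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """Effective first-order coefficients kf·Πc_subs, kr·Πc_prods per step."""
        kf = self.k_plus.copy()
        kr = self.k_minus.copy()
        for i, st in enumerate(self.pattern.steps):
            for m in st.substrates:
                kf[i] *= max(conc[m], 0.0)
            for m in st.products:
                kr[i] *= max(conc[m], 0.0)
        return kf, kr

    def _balance_matrix(self, conc: Mapping[str, float]) -> np.ndarray:
        n = self.pattern.n_states
        A = np.zeros((n, n))
        kf, kr = self._step_coeffs(conc)
        for i, st in enumerate(self.pattern.steps):
            a, b = self._pos[st.source], self._pos[st.target]
            A[b, a] += kf[i]
            A[a, a] -= kf[i]
            A[a, b] += kr[i]
            A[b, b] -= kr[i]
        return A

    def state_abundances(self, conc: Mapping[str, float], e_total: float = 1.0) -> np.ndarray:
        """Pseudo-steady-state intermediate abundances at given concentrations."""
        A = self._balance_matrix(conc)
        n = self.pattern.n_states
        M = np.vstack([A, np.ones(n)])
        rhs = np.zeros(n + 1)
        rhs[-1] = e_total
        e, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        return e

    def step_rates(self, conc: Mapping[str, float],
                   e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-step (forward, reverse) one-way rates at given state abundances."""
        kf, kr = self._step_coeffs(conc)
        src = np.array([self._pos[st.source] for st in self.pattern.steps])
        tgt = np.array([self._pos[st.target] for st in self.pattern.steps])
        return kf * e[src], kr * e[tgt]

    def state_derivatives(self, conc: Mapping[str, float], e: np.ndarray) -> np.ndarray:
        """de/dt of the explicit-intermediates mode (cross-validation of PSS)."""
        return self._balance_matrix(conc) @ np.asarray(e, dtype=float)

    # -- public -------------------------------------------------------------

    def __call__(self, conc: Mapping[str, float], e_total: float = 1.0) -> dict[str, float]:
        e = self.state_abundances(conc, e_total)
        fwd, rev = self.step_rates(conc, e)
        return {rid: float(fwd[i] - rev[i]) for rid, i in self.pattern.flux_step.items()}

    def haldane_product(self, reaction_id: str) -> float:
        """Π k+/k- around the reaction's main catalytic cycle (scaled space)."""
        cyc = self.pattern.cycles[reaction_id]
        return float(np.prod(self.k_plus[cyc] / self.k_minus[cyc]))


class MassActionRate:
    """Net rate k·(Π substrates − r_ref·Π products) in scaled concentrations.

    Used for exchange and cofactor-regeneration reactions.  One-sided
    stoichiometry (pure source or sink) reduces to the irreversible form
    k·Π substrates; a pure source is a constant influx.
    """

    def __init__(self, reaction_id: str,
                 substrates: Sequence[tuple[str, float]],
                 products: Sequence[tuple[str, float]],
                 k: float, r_ref: float):
        self.reaction_id = reaction_id
        self.substrates = tuple(substrates)
        self.products = tuple(products)
        self.k = float(k)
        self.r_ref = float(r_ref)
        self.one_sided = not substrates or not products

    def __call__(self, conc: Mapping[str, float], e_total: float = 1.0) -> dict[str, float]:
        fwd = np.prod([max(conc[m], 0.0) ** c for m, c in self.substrates]) if self.substrates else 1.0
        if self.one_sided:
            rate = self.k * fwd
        else:
            rev = np.prod([max(conc[m], 0.0) ** c for m, c in self.products])
            rate = self.k * (fwd - self.r_ref * rev)
        return {self.reaction_id: float(e_total * rate)}


def mass_action_rate(reaction_id: str,
                     substrates: Sequence[tuple[str, float]],
                     products: Sequence[tuple[str, float]],
                     v_resolved: float, r_ref: float,
                     k_equilibrium: float | None = None) -> MassActionRate:
    """Anchor a mass-action rate law at the reference state.

    Scaled reference concentrations are all 1, so the anchoring equation is
    k·(1 − r_ref) = v for the two-sided form and k = v for one-sided forms.
    Zero-flux reactions use the near-equilibrium convention (r_ref = 1) with a
    sampled positive turnover ``k_equilibrium``.
    """
    one_sided = not substrates or not products
    if v_resolved == 0.0:
        if one_sided:
            k = 0.0
        else:
            if k_equilibrium is None:
                raise MechanismError(
                    f"reaction {reaction_id!r}: zero-flux mass action needs a sampled "
                    f"equilibrium turnover"
                )
            k, r_ref = k_equilibrium, 1.0
    elif one_sided:
        k = v_resolved
        if k < 0:
            raise MechanismError(
                f"reaction {reaction_id!r}: one-sided mass action cannot carry negative flux"
            )
    else:
        if r_ref == 1.0:
            raise MechanismError(
                f"reaction {reaction_id!r}: r_ref = 1 with nonzero flux (dG = 0) is "
                f"thermodynamically inconsistent"
            )
        k = v_resolved / (1.0 - r_ref)
    return MassActionRate(reaction_id, substrates, products, k, r_ref)
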