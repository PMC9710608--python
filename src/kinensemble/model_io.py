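"""Model specification I/O.

A model lives on disk as a directory ("spec bundle") of plain TSV sheets plus a
YAML config, mirroring the sheet vocabulary that practitioners of ensemble
kinetic modelling already use:

``mets.tsv``
    metabolite, name, balanced (1 = mass-balanced/dynamic, 0 = fixed boundary)
``rxns.tsv``
    reaction, mechanism, inhibitors, activators, negEffectors,
    promiscuousGroup, isoenzymeGroup  (list cells are comma-separated)
``stoichiometry.tsv``
    rows = reactions, columns = metabolites (integer coefficients)
``thermoRxns.tsv``
    reaction, dG_min, dG_max  (kJ/mol, Gibbs energy at the reference state)
``thermoMets.tsv``
    metabolite, conc_min, conc_max  (mol/L)
``measRates.tsv``
    id, flux — one row per reaction, except isoenzyme groups which carry a
    single row keyed by the group id (the split between isoenzymes is unknown
    and is sampled later)
``config.yaml``
    sampling configuration (number of models, mode, tolerance, seed, ...)

All floats are written with 17 significant digits so that a write→parse
round-trip is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

MASS_ACTION = "massAction"

#: mechanism names with a built-in elementary-step pattern (see `mechanisms`)
PATTERN_MECHANISMS = ("uniUni", "orderedBiBi", "randomBiBi", "pingPong")

FLOAT_FMT = "%.17g"


class ModelSpecError(ValueError):
    """Raised when a spec bundle is malformed; the message names the record."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    balanced: bool = True


@dataclass(frozen=True)
class Reaction:
    id: str
    mechanism: str = MASS_ACTION
    inhibitors: tuple[str, ...] = ()       # competitive (dead-end) inhibitors
    activators: tuple[str, ...] = ()       # allosteric activators
    neg_effectors: tuple[str, ...] = ()    # allosteric inhibitors
    promiscuous_group: str | None = None
    isoenzyme_group: str | None = None

    @property
    def allosteric(self) -> bool:
        return bool(self.activators or self.neg_effectors)


class NetworkModel:
    """Stoichiometry plus per-reaction mechanism and regulator assignments.

    ``stoichiometry`` has one row per declared metabolite (balanced and fixed)
    and one column per reaction; ``S`` is the balanced-row submatrix used for
    steady-state and conservation analysis.
    """

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        stoichiometry: np.ndarray,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.stoichiometry = np.asarray(stoichiometry, dtype=float)
        if self.stoichiometry.shape != (len(self.metabolites), len(self.reactions)):
            raise ModelSpecError(
                f"stoichiometry shape {self.stoichiometry.shape} does not match "
                f"{len(self.metabolites)} metabolites x {len(self.reactions)} reactions"
            )
        self.met_ids = [m.id for m in self.metabolites]
        self.rxn_ids = [r.id for r in self.reactions]
        self.met_index = {m: i for i, m in enumerate(self.met_ids)}
        self.rxn_index = {r: j for j, r in enumerate(self.rxn_ids)}
        self.balanced_idx = [i for i, m in enumerate(self.metabolites) if m.balanced]

    # -- views --------------------------------------------------------------

    @property
    def S(self) -> np.ndarray:
        """Stoichiometric matrix over balanced metabolites only."""
        return self.stoichiometry[self.balanced_idx, :]

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def substrates(self, rxn: str) -> list[tuple[str, float]]:
        j = self.rxn_index[rxn]
        col = self.stoichiometry[:, j]
        return [(self.met_ids[i], -col[i]) for i in np.nonzero(col < 0)[0]]

    def products(self, rxn: str) -> list[tuple[str, float]]:
        j = self.rxn_index[rxn]
        col = self.stoichiometry[:, j]
        return [(self.met_ids[i], col[i]) for i in np.nonzero(col > 0)[0]]

    def enzyme_id(self, rxn: str) -> str:
        """Identifier of the enzyme pool driving a reaction.

        Reactions in a promiscuous group share one pool (the group id); every
        other reaction has its own enzyme named after the reaction.  Isoenzyme
        group members are distinct enzymes by definition.
        """
        r = self.reactions[self.rxn_index[rxn]]
        return r.promiscuous_group or r.id

    def enzyme_units(self) -> dict[str, list[str]]:
        """Map enzyme id -> reactions catalysed by that single enzyme pool."""
        units: dict[str, list[str]] = {}
        for r in self.reactions:
            if r.mechanism == MASS_ACTION:
                continue
            units.setdefault(self.enzyme_id(r.id), []).append(r.id)
        return units

    def isoenzyme_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for r in self.reactions:
            if r.isoenzyme_group:
                groups.setdefault(r.isoenzyme_group, []).append(r.id)
        return groups

    def promiscuous_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for r in self.reactions:
            if r.promiscuous_group:
                groups.setdefault(r.promiscuous_group, []).append(r.id)
        return groups


@dataclass
class ReferenceState:
    """Reference steady state: fluxes, Gibbs-energy ranges, concentration ranges.

    ``v_ref[j]`` is NaN for isoenzyme-group members; their shared net flux is
    in ``group_flux`` keyed by the group id and is split stochastically when a
    thermodynamic state is sampled.
    """

    v_ref: np.ndarray                      # (n_rxn,) flux units, NaN for iso members
    dG_range: np.ndarray                   # (n_rxn, 2) kJ/mol at the reference state
    conc_range: np.ndarray                 # (n_met, 2) mol/L
    group_flux: dict[str, float] = field(default_factory=dict)
    temperature: float = 298.15            # K

    def copy(self) -> "ReferenceState":
        return ReferenceState(
            v_ref=self.v_ref.copy(),
            dG_range=self.dG_range.copy(),
            conc_range=self.conc_range.copy(),
            group_flux=dict(self.group_flux),
            temperature=self.temperature,
        )

    def nominal_flux(self, model: NetworkModel) -> np.ndarray:
        """Flux vector with isoenzyme group fluxes split equally.

        Used for steady-state validation only; any split gives the same S·v
        because group members share identical stoichiometry.
        """
        v = self.v_ref.copy()
        for gid, members in model.isoenzyme_groups().items():
            share = self.group_flux[gid] / len(members)
            for rid in members:
                v[model.rxn_index[rid]] = share
        return v


@dataclass
class SamplingConfig:
    n_models: int = 100
    mode: str = "prior"                    # "prior" | "rejection"
    tolerance: float | None = None         # ABC distance cutoff (rejection mode)
    seed: int = 0
    max_attempts: int = 10000              # ABC attempt cap
    thermo_max_tries: int = 10000          # accept-reject cap per thermo sample
    # ODE / steady-state numerics
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10
    t_end: float = 1000.0
    ss_tol: float = 1e-9                   # ||dx/dt||_inf / max(||x||_inf,1)
    cond_threshold: float = 1e12           # MCA Jacobian conditioning guard
    # prior hyperparameters
    dirichlet_alpha: float = 1.0
    L_range: tuple[float, float] = (1e-4, 1e4)
    n_protomers_max: int = 4
    K_eff_range: tuple[float, float] = (1e-2, 1e2)
    exchange_flux_range: tuple[float, float] = (0.1, 10.0)  # x median |flux|

    def __post_init__(self):
        if self.n_models < 1:
            raise ModelSpecError("n_models must be >= 1")
        if self.mode not in ("prior", "rejection"):
            raise ModelSpecError(f"unknown mode {self.mode!r}")
        if self.mode == "rejection" and self.tolerance is None:
            raise ModelSpecError("tolerance is required in rejection mode")


@dataclass(frozen=True)
class Diagnostic:
    severity: str      # "ERROR" | "WARNING"
    code: str
    message: str


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_SHEETS = (
    "mets.tsv", "rxns.tsv", "stoichiometry.tsv",
    "thermoRxns.tsv", "thermoMets.tsv", "measRates.tsv",
)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _split_list(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(tok.strip() for tok in cell.split(",") if tok.strip())


def _to_float(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ModelSpecError(f"non-numeric value {cell!r} in {where}") from None


def parse_model_spec(path: str | Path) -> tuple[NetworkModel, ReferenceState, SamplingConfig]:
    """Read a spec bundle directory into a validated (model, ref, config) triple.

    Deterministic (no sampling).  Raises :class:`ModelSpecError` naming the
    offending sheet/record on any inconsistency.
    """
    d = Path(path)
    for sheet in _SHEETS:
        if not (d / sheet).exists():
            raise ModelSpecError(f"missing sheet {sheet} in {d}")

    mets_df = _read_tsv(d / "mets.tsv")
    mets: list[Metabolite] = []
    seen: set[str] = set()
    for _, row in mets_df.iterrows():
        mid = row["metabolite"].strip()
        if mid in seen:
            raise ModelSpecError(f"duplicated metabolite id {mid!r} in mets.tsv")
        seen.add(mid)
        mets.append(Metabolite(mid, row.get("name", ""), row["balanced"].strip() == "1"))
    met_ids = {m.id for m in mets}

    rxns_df = _read_tsv(d / "rxns.tsv")
    rxns: list[Reaction] = []
    seen = set()
    for _, row in rxns_df.iterrows():
        rid = row["reaction"].strip()
        if rid in seen:
            raise ModelSpecError(f"duplicated reaction id {rid!r} in rxns.tsv")
        seen.add(rid)
        mech = row["mechanism"].strip()
        if mech != MASS_ACTION and mech not in PATTERN_MECHANISMS:
            raise ModelSpecError(f"unknown mechanism {mech!r} for reaction {rid!r}")
        regs = {
            "inhibitors": _split_list(row.get("inhibitors", "")),
            "activators": _split_list(row.get("activators", "")),
            "neg_effectors": _split_list(row.get("negEffectors", "")),
        }
        for kind, lst in regs.items():
            for m in lst:
                if m not in met_ids:
                    raise ModelSpecError(
                        f"reaction {rid!r} references undeclared metabolite {m!r} as {kind[:-1]}"
                    )
        rxns.append(Reaction(
            rid, mech,
            inhibitors=regs["inhibitors"],
            activators=regs["activators"],
            neg_effectors=regs["neg_effectors"],
            promiscuous_group=row.get("promiscuousGroup", "").strip() or None,
            isoenzyme_group=row.get("isoenzymeGroup", "").strip() or None,
        ))
    rxn_ids = [r.id for r in rxns]

    stoich_df = _read_tsv(d / "stoichiometry.tsv")
    stoich_cols = [c for c in stoich_df.columns if c != "reaction"]
    for c in stoich_cols:
        if c not in met_ids:
            raise ModelSpecError(f"stoichiometry column {c!r} is not a declared metabolite")
    S = np.zeros((len(mets), len(rxns)))
    met_pos = {m.id: i for i, m in enumerate(mets)}
    stoich_rxns = list(stoich_df["reaction"].str.strip())
    if set(stoich_rxns) != set(rxn_ids):
        extra = set(stoich_rxns) - set(rxn_ids)
        missing = set(rxn_ids) - set(stoich_rxns)
        raise ModelSpecError(
            f"stoichiometry reactions mismatch (unknown: {sorted(extra)}, missing: {sorted(missing)})"
        )
    for _, row in stoich_df.iterrows():
        j = rxn_ids.index(row["reaction"].strip())
        for c in stoich_cols:
            S[met_pos[c], j] = _to_float(row[c] or "0", f"stoichiometry.tsv row {row['reaction']!r}")

    model = NetworkModel(mets, rxns, S)

    thermo_r = _read_tsv(d / "thermoRxns.tsv")
    dG_range = np.full((len(rxns), 2), np.nan)
    for _, row in thermo_r.iterrows():
        rid = row["reaction"].strip()
        if rid not in model.rxn_index:
            raise ModelSpecError(f"thermoRxns.tsv references unknown reaction {rid!r}")
        j = model.rxn_index[rid]
        lo = _to_float(row["dG_min"], f"thermoRxns.tsv {rid!r}")
        hi = _to_float(row["dG_max"], f"thermoRxns.tsv {rid!r}")
        if lo > hi:
            raise ModelSpecError(f"dG_min > dG_max for reaction {rid!r}")
        dG_range[j] = (lo, hi)
    if np.isnan(dG_range).any():
        missing_r = [rxn_ids[j] for j in np.nonzero(np.isnan(dG_range[:, 0]))[0]]
        raise ModelSpecError(f"thermoRxns.tsv missing reactions {missing_r}")

    thermo_m = _read_tsv(d / "thermoMets.tsv")
    conc_range = np.full((len(mets), 2), np.nan)
    for _, row in thermo_m.iterrows():
        mid = row["metabolite"].strip()
        if mid not in model.met_index:
            raise ModelSpecError(f"thermoMets.tsv references unknown metabolite {mid!r}")
        i = model.met_index[mid]
        lo = _to_float(row["conc_min"], f"thermoMets.tsv {mid!r}")
        hi = _to_float(row["conc_max"], f"thermoMets.tsv {mid!r}")
        if not (0 < lo <= hi):
            raise ModelSpecError(f"invalid concentration range for metabolite {mid!r}")
        conc_range[i] = (lo, hi)
    if np.isnan(conc_range).any():
        missing_m = [model.met_ids[i] for i in np.nonzero(np.isnan(conc_range[:, 0]))[0]]
        raise ModelSpecError(f"thermoMets.tsv missing metabolites {missing_m}")

    rates = _read_tsv(d / "measRates.tsv")
    v_ref = np.full(len(rxns), np.nan)
    group_flux: dict[str, float] = {}
    groups = model.isoenzyme_groups()
    member_rxns = {rid for members in groups.values() for rid in members}
    for _, row in rates.iterrows():
        key = row["id"].strip()
        val = _to_float(row["flux"], f"measRates.tsv {key!r}")
        if key in groups:
            group_flux[key] = val
        elif key in model.rxn_index:
            if key in member_rxns:
                raise ModelSpecError(
                    f"measRates.tsv: isoenzyme member {key!r} must not carry its own flux; "
                    f"give the group flux instead"
                )
            v_ref[model.rxn_index[key]] = val
        else:
            raise ModelSpecError(f"measRates.tsv references unknown id {key!r}")
    for gid in groups:
        if gid not in group_flux:
            raise ModelSpecError(f"measRates.tsv missing flux for isoenzyme group {gid!r}")
    non_member = [j for j, rid in enumerate(rxn_ids) if rid not in member_rxns]
    if np.isnan(v_ref[non_member]).any():
        missing_v = [rxn_ids[j] for j in non_member if math.isnan(v_ref[j])]
        raise ModelSpecError(f"measRates.tsv missing fluxes for reactions {missing_v}")

    ref = ReferenceState(v_ref=v_ref, dG_range=dG_range, conc_range=conc_range,
                         group_flux=group_flux)

    cfg_path = d / "config.yaml"
    config = SamplingConfig()
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in SamplingConfig.__dataclass_fields__}
        unknown = set(raw) - known - {"temperature"}
        if unknown:
            raise ModelSpecError(f"unknown config keys {sorted(unknown)}")
        if "temperature" in raw:
            ref.temperature = float(raw.pop("temperature"))
        for k in ("L_range", "K_eff_range", "exchange_flux_range"):
            if k in raw:
                raw[k] = tuple(float(x) for x in raw[k])
        config = SamplingConfig(**raw)

    _check_structure(model)
    return model, ref, config


def _check_structure(model: NetworkModel) -> None:
    for gid, members in model.isoenzyme_groups().items():
        cols = [model.stoichiometry[:, model.rxn_index[r]] for r in members]
        for c in cols[1:]:
            if not np.array_equal(cols[0], c):
                raise ModelSpecError(
                    f"isoenzyme group {gid!r} members do not share identical stoichiometry"
                )
        if len(members) < 2:
            raise ModelSpecError(f"isoenzyme group {gid!r} has a single member")
    for r in model.reactions:
        if r.promiscuous_group and r.mechanism == MASS_ACTION:
            raise ModelSpecError(
                f"reaction {r.id!r}: mass-action reactions cannot join promiscuous group "
                f"{r.promiscuous_group!r}"
            )


# ---------------------------------------------------------------------------
# writing (round-trip + fixture emission)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def write_model_spec(model: NetworkModel, ref: ReferenceState, config: SamplingConfig,
                     path: str | Path) -> Path:
    """Write the triple as a spec bundle directory (inverse of parse_model_spec)."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)

    pd.DataFrame({
        "metabolite": [m.id for m in model.metabolites],
        "name": [m.name for m in model.metabolites],
        "balanced": ["1" if m.balanced else "0" for m in model.metabolites],
    }).to_csv(d / "mets.tsv", sep="\t", index=False)

    pd.DataFrame({
        "reaction": [r.id for r in model.reactions],
        "mechanism": [r.mechanism for r in model.reactions],
        "inhibitors": [",".join(r.inhibitors) for r in model.reactions],
        "activators": [",".join(r.activators) for r in model.reactions],
        "negEffectors": [",".join(r.neg_effectors) for r in model.reactions],
        "promiscuousGroup": [r.promiscuous_group or "" for r in model.reactions],
        "isoenzymeGroup": [r.isoenzyme_group or "" for r in model.reactions],
    }).to_csv(d / "rxns.tsv", sep="\t", index=False)

    stoich = pd.DataFrame(model.stoichiometry.T, columns=model.met_ids)
    stoich = stoich.map(lambda x: _fmt(x) if x else "0")
    stoich.insert(0, "reaction", model.rxn_ids)
    stoich.to_csv(d / "stoichiometry.tsv", sep="\t", index=False)

    pd.DataFrame({
        "reaction": model.rxn_ids,
        "dG_min": [_fmt(x) for x in ref.dG_range[:, 0]],
        "dG_max": [_fmt(x) for x in ref.dG_range[:, 1]],
    }).to_csv(d / "thermoRxns.tsv", sep="\t", index=False)

    pd.DataFrame({
        "metabolite": model.met_ids,
        "conc_min": [_fmt(x) for x in ref.conc_range[:, 0]],
        "conc_max": [_fmt(x) for x in ref.conc_range[:, 1]],
    }).to_csv(d / "thermoMets.tsv", sep="\t", index=False)

    member_rxns = {rid for ms in model.isoenzyme_groups().values() for rid in ms}
    ids, fluxes = [], []
    for j, rid in enumerate(model.rxn_ids):
        if rid not in member_rxns:
            ids.append(rid)
            fluxes.append(_fmt(ref.v_ref[j]))
    for gid, fv in ref.group_flux.items():
        ids.append(gid)
        fluxes.append(_fmt(fv))
    pd.DataFrame({"id": ids, "flux": fluxes}).to_csv(d / "measRates.tsv", sep="\t", index=False)

    cfg = {
        "n_models": config.n_models,
        "mode": config.mode,
        "seed": config.seed,
        "temperature": ref.temperature,
    }
    if config.tolerance is not None:
        cfg["tolerance"] = config.tolerance
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return d


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

STEADY_STATE_TOL = 1e-9


def validate_model(model: NetworkModel, ref: ReferenceState,
                   ss_tol: float = STEADY_STATE_TOL) -> list[Diagnostic]:
    """Cross-check the triple; returns [] iff fully consistent.

    Checks structural invariants, the steady-state condition ||S·v_ref||_inf,
    and the flux-direction rule: every flux-carrying reaction's dG range must
    reach the side of zero opposite to its flux sign.
    """
    diags: list[Diagnostic] = []
    v = ref.nominal_flux(model)

    resid = np.abs(model.S @ v)
    if resid.size and resid.max() > ss_tol * max(1.0, np.abs(v).max()):
        worst = model.met_ids[model.balanced_idx[int(np.argmax(resid))]]
        diags.append(Diagnostic(
            "ERROR", "not-steady-state",
            f"reference fluxes are not at steady state: |S·v| = {resid.max():.3g} "
            f"at metabolite {worst!r}",
        ))

    for j, rid in enumerate(model.rxn_ids):
        lo, hi = ref.dG_range[j]
        vj = v[j]
        if vj > 0 and lo >= 0:
            diags.append(Diagnostic(
                "ERROR", "thermo-infeasible-direction",
                f"reaction {rid!r}: v_ref > 0 but dG range [{lo}, {hi}] excludes negative values "
                f"(thermodynamically infeasible direction)",
            ))
        elif vj < 0 and hi <= 0:
            diags.append(Diagnostic(
                "ERROR", "thermo-infeasible-direction",
                f"reaction {rid!r}: v_ref < 0 but dG range [{lo}, {hi}] excludes positive values "
                f"(thermodynamically infeasible direction)",
            ))

    if (ref.conc_range[:, 0] <= 0).any():
        bad = [model.met_ids[i] for i in np.nonzero(ref.conc_range[:, 0] <= 0)[0]]
        diags.append(Diagnostic("ERROR", "conc-range-nonpositive",
                                f"non-positive concentration ranges for {bad}"))
    if (ref.dG_range[:, 0] > ref.dG_range[:, 1]).any():
        bad = [model.rxn_ids[j] for j in np.nonzero(ref.dG_range[:, 0] > ref.dG_range[:, 1])[0]]
        diags.append(Diagnostic("ERROR", "dg-range-inverted", f"inverted dG ranges for {bad}"))

    try:
        _check_structure(model)
    except ModelSpecError as exc:
        diags.append(Diagnostic("ERROR", "structure", str(exc)))

    for gid, members in model.isoenzyme_groups().items():
        if gid in ref.group_flux and ref.group_flux[gid] == 0:
            diags.append(Diagnostic("WARNING", "iso-zero-flux",
                                    f"isoenzyme group {gid!r} carries zero net flux"))
    return diags
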