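"""Ensemble orchestration: prior sampling, ABC rejection, model selection.

Sampling a model = drawing a thermodynamic state, then a kinetic
parameterization anchored at it.  Each model in an ensemble gets its own
random generator derived from the master seed and the model's attempt index
(counter-based seeding), so ensembles are bit-reproducible and independent of
any worker partitioning.

ABC rejection simulates every observed condition with each prior draw and
keeps draws whose root-mean-square of SD-standardized residuals (fluxes on
their natural scale, concentrations on log scale) is within the tolerance.
Model selection runs the same rejection stream for each candidate structure
under a common attempt budget; acceptance-frequency ratios estimate posterior
odds under a uniform model prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import Perturbation, steady_state
from .model_io import NetworkModel, ReferenceState, SamplingConfig
from .param_sampling import (
    AllostericParams, EnzymeUnitParams, KineticParameterization,
    build_model_patterns, sample_parameterization,
)
from .mechanisms import MassActionRate
from .thermo import ThermoSample, sample_thermo_state, tighten_dg_bounds


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

@dataclass
class Condition:
    """One steady-state condition: perturbations applied + quantities measured."""
    name: str
    enzyme_folds: dict[str, float] = field(default_factory=dict)
    fluxes: dict[str, tuple[float, float]] = field(default_factory=dict)         # id -> (value, sd)
    concentrations: dict[str, tuple[float, float]] = field(default_factory=dict)  # scaled; sd on log scale
    enzymes_measured: dict[str, tuple[float, float]] = field(default_factory=dict)

    def n_measured(self) -> int:
        return len(self.fluxes) + len(self.concentrations) + len(self.enzymes_measured)


@dataclass
class ObservationSet:
    conditions: list[Condition]

    def __post_init__(self):
        for c in self.conditions:
            if c.n_measured() == 0:
                raise ValueError(f"condition {c.name!r} has no measured quantity")
            for group in (c.fluxes, c.concentrations, c.enzymes_measured):
                for key, (_, sd) in group.items():
                    if not sd > 0:
                        raise ValueError(f"condition {c.name!r}: SD for {key!r} must be > 0")


def write_observations(obs: ObservationSet, path: str | Path) -> Path:
    """One TSV per condition: kind (flux|conc|enzyme), id, value, sd, use."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    for c in obs.conditions:
        rows = []
        for eid, fold in c.enzyme_folds.items():
            rows.append(("enzyme", eid, fold, "", "perturb"))
        for rid, (val, sd) in c.fluxes.items():
            rows.append(("flux", rid, val, sd, "fit"))
        for mid, (val, sd) in c.concentrations.items():
            rows.append(("conc", mid, val, sd, "fit"))
        for eid, (val, sd) in c.enzymes_measured.items():
            rows.append(("enzyme", eid, val, sd, "fit"))
        pd.DataFrame(rows, columns=["kind", "id", "value", "sd", "use"]).to_csv(
            d / f"{c.name}.tsv", sep="\t", index=False)
    return d


def read_observations(path: str | Path) -> ObservationSet:
    d = Path(path)
    conditions = []
    for f in sorted(d.glob("*.tsv")):
        cond = Condition(name=f.stem)
        df = pd.read_csv(f, sep="\t", dtype={"id": str, "kind": str, "use": str})
        for _, row in df.iterrows():
            kind, use = row["kind"], row["use"]
            if kind == "enzyme" and use == "perturb":
                cond.enzyme_folds[row["id"]] = float(row["value"])
            elif kind == "flux":
                cond.fluxes[row["id"]] = (float(row["value"]), float(row["sd"]))
            elif kind == "conc":
                cond.concentrations[row["id"]] = (float(row["value"]), float(row["sd"]))
            elif kind == "enzyme":
                cond.enzymes_measured[row["id"]] = (float(row["value"]), float(row["sd"]))
            else:
                raise ValueError(f"{f.name}: unknown record kind {kind!r}")
        conditions.append(cond)
    return ObservationSet(conditions)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class ModelEnsemble:
    models: list[KineticParameterization]
    seed: int
    mode: str
    tolerance: float | None = None
    n_attempted: int = 0
    distances: list[float] | None = None
    n_divergent: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.models)


def _model_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def sample_prior_ensemble(model: NetworkModel, ref: ReferenceState,
                          config: SamplingConfig) -> ModelEnsemble:
    """Sample exactly n_models independent, anchored parameterizations."""
    tightened = tighten_dg_bounds(model, ref)
    patterns = build_model_patterns(model)
    models = []
    for i in range(config.n_models):
        rng = _model_rng(config.seed, i)
        ts = sample_thermo_state(model, tightened, rng, max_tries=config.thermo_max_tries)
        models.append(sample_parameterization(model, patterns, ts, config, rng))
    return ModelEnsemble(models=models, seed=config.seed, mode="prior",
                         n_attempted=config.n_models)


@dataclass
class PredictedState:
    fluxes: np.ndarray
    conc: np.ndarray          # scaled, all metabolites
    converged: bool


def predict_condition(model: NetworkModel, params: KineticParameterization,
                      condition: Condition,
                      config: SamplingConfig | None = None) -> PredictedState:
    """Steady state of the ODE system under the condition's enzyme fold-changes."""
    cfg = config or SamplingConfig()
    try:
        traj = steady_state(model, params,
                            Perturbation(enzyme_folds=dict(condition.enzyme_folds)),
                            config=cfg)
    except (RuntimeError, FloatingPointError, np.linalg.LinAlgError):
        n = model.n_metabolites
        return PredictedState(np.full(model.n_reactions, np.nan), np.full(n, np.nan), False)
    ok = traj.converged and np.isfinite(traj.conc[-1]).all()
    return PredictedState(traj.rates[-1], traj.conc[-1], ok)


def abc_distance(predictions: Mapping[str, PredictedState],
                 observed: ObservationSet, model: NetworkModel) -> float:
    """RMS of SD-standardized residuals over all measurements and conditions.

    Fluxes on their natural scale; concentrations on log scale; measured enzyme
    levels compared to the applied fold-change.  Non-converged predictions give
    an infinite distance.  Symmetric under condition reordering (the RMS pools
    all residuals) and zero iff every prediction equals its observation.
    """
    res = []
    for cond in observed.conditions:
        if cond.name not in predictions:
            continue
        pred = predictions[cond.name]
        if not pred.converged:
            return math.inf
        for rid, (val, sd) in cond.fluxes.items():
            res.append((pred.fluxes[model.rxn_index[rid]] - val) / sd)
        for mid, (val, sd) in cond.concentrations.items():
            p = pred.conc[model.met_index[mid]]
            if p <= 0 or val <= 0:
                return math.inf
            res.append((math.log(p) - math.log(val)) / sd)
        for eid, (val, sd) in cond.enzymes_measured.items():
            res.append((cond.enzyme_folds.get(eid, 1.0) - val) / sd)
    if not res:
        raise ValueError("no overlap between predicted and observed quantities")
    r = np.asarray(res)
    return float(np.sqrt(np.mean(r * r)))


def _evaluate_attempt(model, tightened, patterns, observations, config, rng):
    ts = sample_thermo_state(model, tightened, rng, max_tries=config.thermo_max_tries)
    params = sample_parameterization(model, patterns, ts, config, rng)
    preds = {c.name: predict_condition(model, params, c, config)
             for c in observations.conditions}
    return params, abc_distance(preds, observations, model)


def abc_rejection(model: NetworkModel, ref: ReferenceState,
                  observations: ObservationSet, config: SamplingConfig,
                  n_attempts: int | None = None,
                  stop_at_n_models: bool = True) -> ModelEnsemble:
    """ABC rejection: keep prior draws whose distance is within the tolerance.

    The attempt stream is fixed by the seed (attempt i uses the generator
    derived from (seed, i)), so the accepted set at a larger tolerance is a
    superset of the set at a smaller one over the same stream.
    """
    if config.tolerance is None:
        raise ValueError("rejection mode requires a tolerance")
    tightened = tighten_dg_bounds(model, ref)
    patterns = build_model_patterns(model)
    accepted, distances = [], []
    n_divergent = 0
    best = math.inf
    budget = n_attempts if n_attempts is not None else config.max_attempts
    attempts = 0
    for i in range(budget):
        attempts = i + 1
        rng = _model_rng(config.seed, i)
        params, dist = _evaluate_attempt(model, tightened, patterns,
                                         observations, config, rng)
        best = min(best, dist)
        if math.isinf(dist):
            n_divergent += 1
        if dist <= config.tolerance:
            accepted.append(params)
            distances.append(dist)
            if stop_at_n_models and len(accepted) >= config.n_models:
                break
    if not accepted:
        raise RuntimeError(
            f"ABC rejection accepted no model in {attempts} attempts "
            f"(best distance achieved: {best:.4g}, tolerance {config.tolerance:g})"
        )
    return ModelEnsemble(models=accepted, seed=config.seed, mode="rejection",
                         tolerance=config.tolerance, n_attempted=attempts,
                         distances=distances, n_divergent=n_divergent)


def model_selection(candidates: Sequence[tuple[str, NetworkModel, ReferenceState]],
                    observations: ObservationSet,
                    config: SamplingConfig,
                    n_attempts: int | None = None) -> pd.DataFrame:
    """Approximate Bayesian model choice over candidate structures.

    Each candidate gets the same attempt budget and seed; acceptance
    frequencies estimate marginal ABC posterior probabilities under a uniform
    model prior, reported together with odds relative to the best candidate.
    Candidates whose thermodynamics are infeasible get frequency 0.
    """
    from .thermo import ThermodynamicInfeasibilityError

    budget = n_attempts if n_attempts is not None else config.max_attempts
    rows = []
    for name, net, ref in candidates:
        try:
            ens = abc_rejection(net, ref, observations, config,
                                n_attempts=budget, stop_at_n_models=False)
            n_acc, n_att = ens.n_accepted, ens.n_attempted
        except (ThermodynamicInfeasibilityError, RuntimeError):
            n_acc, n_att = 0, budget
        rows.append({"candidate": name, "n_attempted": n_att, "n_accepted": n_acc,
                     "acceptance_rate": n_acc / n_att if n_att else 0.0})
    df = pd.DataFrame(rows)
    best = df["acceptance_rate"].max()
    df["posterior_odds"] = df["acceptance_rate"] / best if best > 0 else 0.0
    return df


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: ModelEnsemble, path: str | Path) -> Path:
    """Serialize an ensemble to a single JSON archive (arrays as lists)."""
    def params_to_dict(p: KineticParameterization) -> dict:
        return {
            "thermo": {
                "dG": p.thermo.dG.tolist(),
                "conc_ref": p.thermo.conc_ref.tolist(),
                "v_resolved": p.thermo.v_resolved.tolist(),
                "temperature": p.thermo.temperature,
            },
            "enzyme_units": {
                eid: {
                    "e_ref": u.e_ref.tolist(),
                    "zeta": u.zeta.tolist(),
                    "step_r": u.step_r.tolist(),
                    "k_plus": u.k_plus.tolist(),
                    "k_minus": u.k_minus.tolist(),
                } for eid, u in p.enzyme_units.items()
            },
            "mass_action": {rid: {"k": fn.k, "r_ref": fn.r_ref}
                            for rid, fn in p.mass_action.items()},
            "allosteric": {rid: {"L": a.L, "n_protomers": a.n_protomers,
                                 "K_act": a.K_act, "K_inh": a.K_inh}
                           for rid, a in p.allosteric.items()},
        }

    doc = {
        "format": "kinensemble-ensemble-v1",
        "seed": ensemble.seed,
        "mode": ensemble.mode,
        "tolerance": ensemble.tolerance,
        "n_attempted": ensemble.n_attempted,
        "n_divergent": ensemble.n_divergent,
        "distances": ensemble.distances,
        "models": [params_to_dict(p) for p in ensemble.models],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _nan_safe(o):
        if isinstance(o, float) and not math.isfinite(o):
            return None
        raise TypeError(o)

    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=_nan_safe)
    return path


def load_ensemble(path: str | Path, model: NetworkModel) -> ModelEnsemble:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "kinensemble-ensemble-v1":
        raise ValueError(f"{path}: not a kinensemble ensemble archive")
    patterns = build_model_patterns(model)
    models = []
    for m in doc["models"]:
        ts = ThermoSample(
            dG=np.array(m["thermo"]["dG"]),
            conc_ref=np.array(m["thermo"]["conc_ref"]),
            v_resolved=np.array(m["thermo"]["v_resolved"]),
            temperature=m["thermo"]["temperature"],
        )
        units = {}
        for eid, u in m["enzyme_units"].items():
            units[eid] = EnzymeUnitParams(
                pattern=patterns[eid],
                e_ref=np.array(u["e_ref"]),
                zeta=np.array(u["zeta"], dtype=float),
                step_r=np.array(u["step_r"], dtype=float),
                k_plus=np.array(u["k_plus"]),
                k_minus=np.array(u["k_minus"]),
            )
        ma = {}
        for rid, d in m["mass_action"].items():
            ma[rid] = MassActionRate(rid, model.substrates(rid), model.products(rid),
                                     d["k"], d["r_ref"])
        allo = {rid: AllostericParams(L=a["L"], n_protomers=a["n_protomers"],
                                      K_act=a["K_act"], K_inh=a["K_inh"])
                for rid, a in m["allosteric"].items()}
        models.append(KineticParameterization(thermo=ts, enzyme_units=units,
                                              mass_action=ma, allosteric=allo))
    return ModelEnsemble(models=models, seed=doc["seed"], mode=doc["mode"],
                         tolerance=doc["tolerance"], n_attempted=doc["n_attempted"],
                         distances=doc["distances"], n_divergent=doc["n_divergent"])
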