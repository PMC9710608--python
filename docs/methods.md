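# Methods

## Scope and model class

`kinensemble` builds populations of kinetic models of metabolic networks in
which every member is exact at a user-supplied reference steady state and
exactly thermodynamically consistent. The inputs are a stoichiometric matrix
with balanced/boundary flags, a reference flux distribution `v_ref` (with
isoenzyme groups carrying a single group flux), per-reaction ranges for the
Gibbs energy of reaction *at the reference state* (kJ/mol,
concentration-included — only the at-state value determines the flux
direction), per-metabolite physiological concentration ranges (mol/L), a
catalytic mechanism per reaction, and lists of competitive inhibitors and
allosteric effectors. All kinetics are expressed in scaled space: metabolite
concentrations and enzyme levels relative to the (sampled) reference, where
every scaled input is 1.

## Thermodynamic layer

Feasibility is a hard constraint, not a statistical tendency:

* **Direction rule.** sign(ΔG_r) = −sign(v) for every flux-carrying reaction.
* **Loop law.** For every internal flux loop λ (null vector of the full
  stoichiometric matrix restricted to reactions with both substrates and
  products), λᵀ·ΔG = 0. One-sided columns (pure sources/sinks) are excluded:
  their implicit external species break any apparent cycle. Concentration
  ranges alone cannot constrain at-state reaction energies further when
  standard formation energies are unknown, so no concentration-mediated
  coupling is imposed beyond the loop law.

`tighten_dg_bounds` intersects each range with the direction half-line (a
1e-6 kJ/mol margin keeps ranges strictly one-sided) and then runs two LPs per
reaction (HiGHS via `scipy.optimize.linprog`) to find the attainable extremes
under the joint constraint set; the result is a non-empty subset of the input
ranges and the operation is idempotent. Infeasibility is reported naming the
offending reaction.

`sample_thermo_state` draws reference concentrations log-uniformly in their
ranges and Gibbs energies uniformly in the tightened boxes. In networks with
loops the box draw is projected orthogonally onto the loop-law subspace and
re-drawn (up to 10,000 tries) until all box and sign constraints hold — exact
uniformity in loop-free networks (all shipped fixtures), approximate
otherwise. Isoenzyme group fluxes are split by a flat Dirichlet over members
(the least-informative prior for an unknown split). Zero-flux reactions draw
ΔG from the full, sign-unconstrained range; their kinetics use the
equilibrium convention below.

The reversibility r = exp(ΔG_r/RT) (R = 8.314e-3 kJ/mol/K, T default
298.15 K) is the single thermodynamic anchor passed to the kinetic layer.

## Kinetic parameterization

Mechanisms are elementary-step patterns with canonical state names (free
enzyme first). Built-ins: uni-uni (3 steps), ordered bi-bi (5 steps through
E, EA, EAB, EPQ, EQ), random bi-bi (both binding orders, branched), ping-pong
(4 steps), plus user-defined linear cycles from a step-list table.
Competitive inhibitors bind the free enzyme as dead-end complexes (no
partial catalysis). Promiscuous enzymes merge several cycles around one
shared free-enzyme state, so total-enzyme conservation couples the branch
rates.

Per model and enzyme:

1. **Abundances** e_ref ~ flat Dirichlet over the pattern's states
   (hyperparameter α exposed in the config; α = 1 default).
2. **Gibbs partition** ζ ~ flat Dirichlet over the main-cycle steps;
   r_i = exp(ζ_i·ΔG_r/RT), so Π r_i equals the overall reversibility exactly
   and every r_i sits on the same side of 1. Parallel branch paths receive
   the same total Gibbs drop as the path they shortcut, re-partitioned
   within the branch — the Wegscheider condition holds exactly.
3. **Back-calculation.** Each step with net flux f (branch fluxes drawn
   uniformly on the simplex; unbranched steps carry the reaction flux) is
   decomposed into one-way fluxes w⁺ = f/(1−r_i), w⁻ = w⁺·r_i, and
   k⁺ = w⁺/e_src, k⁻ = w⁻/e_tgt at scaled reference concentrations 1.
   Because the assigned step fluxes balance at every enzyme state, e_ref is
   the exact pseudo-steady-state solution at the reference — anchoring holds
   to machine precision, and Haldane products follow from the partition.
   Dead-end and zero-flux steps are at equilibrium with a sampled one-way
   turnover, log-uniform on [0.1, 10] × the median network flux magnitude
   (some turnover is needed for finite elasticities).
4. **Mass action.** Two-sided: v = k(Π s − r_ref Π p) with k = v/(1−r_ref);
   one-sided exchanges reduce to k·Π s; zero-flux reactions take r_ref = 1
   and a sampled equilibrium k.
5. **Allostery.** Two-state MWC layer: factor = 1/(1+L_eff),
   L_eff = L·[(1+Σ inh/K_inh)/(1+Σ act/K_act)]^n. Priors: L log-uniform on
   [1e-4, 1e4], n uniform on {1..4}, effector constants log-uniform on
   [1e-2, 1e2] (scaled). The catalytic rate is multiplied by
   factor/factor_ref so regulation never breaks anchoring. The exact MWC
   variant is isolated behind `regulatory_factor` so alternatives can be
   swapped.

Rates are evaluated by solving the linear enzyme-intermediate balance at the
given metabolite concentrations (pseudo-steady state), so the dynamic system
lives in metabolite space only; `RateFunction.state_derivatives` provides the
explicit-intermediates mode used to cross-validate the reduction.

## Ensembles, ABC, model selection

Model i of an ensemble uses the generator seeded by `SeedSequence(seed,
spawn_key=(i,))` — counter-based, so ensembles are bit-reproducible and
independent of worker partitioning, and the rejection sampler's attempt
stream is fixed: the accepted set at a larger tolerance is a superset of the
set at a smaller one.

The ABC distance is the RMS of SD-standardized residuals pooled over all
measurements and conditions — fluxes on their natural scale, concentrations
on log scale, measured enzyme levels against the applied fold-change (enzyme
records are flagged per row as perturbation or fitted quantity).
Non-converging simulations receive infinite distance (counted separately):
a divergent model is consistent with no steady-state observation. Rejection
uses a single tolerance (no SMC ladder; a ladder is a documented extension
point). Model selection runs the same attempt budget and seed per candidate
structure; acceptance-frequency ratios approximate posterior odds under a
uniform model prior. The tolerance is chosen, as is standard for ABC
rejection, so the prior acceptance rate is moderate (a few to a few tens of
percent) relative to the observed distance scale.

## Analysis

Conserved moieties are handled with an exact (rational-arithmetic) link
decomposition S = L·N_r; dynamics integrate only independent metabolites and
reconstruct the rest. Elasticities are central finite differences in
log-concentration space (relative step 1e-6); mass-action reactions also have
analytic elasticities used as a cross-check (agreement required at 1e-4).
Zero-flux rows fall back to unscaled derivatives and are flagged. Control
coefficients use the reduced Jacobian:
C^S = −(N̂_r·(∂v/∂x)·L̂)⁻¹·N̂_r·diag(v), C^J = I + ε·L̂·C^S, defined with
respect to enzyme-activity perturbations; an ill-conditioned Jacobian
(condition number above 1e12, configurable) raises an error naming the
near-zero mode. Time courses integrate with LSODA (rtol 1e-8, atol 1e-10
defaults); steady state is declared when ‖dx/dt‖∞/max(‖x‖∞, 1) < 1e-9, and
`steady_state` adds a Newton polish of the endpoint. Concentrations are
clipped at zero inside rate evaluations as a negative-concentration guard.

When comparing control coefficients to perturbation simulations, the checks
use the *symmetric* ±1% enzyme response (average of up- and down-
perturbation), which cancels the genuine O(δ²) curvature of the one-sided
response (measured up to ~2% of the signal for some sampled models) and
isolates the derivative the theorems state; agreement is required at 2%.

## Synthetic fixtures: what they emulate and what they do not

`make_linear_chain` is a boundary-fed uni-uni pathway at a uniform flux with
strictly negative Gibbs ranges ([−25, −1] kJ/mol) and physiological
concentration ranges (5e-5 to 5e-3 mol/L) — the minimal system with
non-trivial control structure. `make_casestudy_shape` reproduces the
structural complexity of a realistic central-carbon model — 79 reactions of
which 27 mass-action exchanges/regenerations and 52 mechanistic, one
isoenzyme pair, seven promiscuous enzymes, competitive inhibitors, allosteric
effectors, a conserved NAD/NADH pool, and all four built-in mechanisms — as
thirteen parallel pathways (fluxes 0.6–1.8) coupled through the cofactor
pool; its kinetic content is synthetic. `generate_observations` simulates a
known-truth parameterization under enzyme fold-changes and adds Gaussian
noise (additive on fluxes, on the log scale for concentrations).

Passing tests on these fixtures demonstrate the machinery (anchoring,
feasibility, inference self-consistency, MCA identities), not biological
realism: real data have correlated noise, missing measurements, model
misspecification, and flux distributions far from uniform pathways. The
problem sizes used in tests and in `scripts/acceptance.py` (ensembles of
100 models, chains of 3–4 reactions for ABC studies, 30-attempt selection
budgets) were chosen to exercise every code path at desk scale.

## Design choices on genuinely open points

* The input spec is a plain TSV bundle plus YAML config (diffable, no
  spreadsheet dependency), mirroring the familiar sheet names
  (`stoichiometry`, `mets`, `rxns`, `thermoRxns`, `thermoMets`, `measRates`).
* SBML export (Level 3 Version 1) writes one species per metabolite and
  enzyme intermediate, one reversible reaction per elementary step with its
  mass-action law in local parameters, the scaled-unit convention recorded
  as annotations, and each reaction's flux-carrying step annotated.
  Allosteric constants are carried as annotations rather than encoded in the
  kinetic law, keeping the laws pure mass action. A structural consistency
  checker runs on every export; import supports the package's own documents
  (round-trips are byte-idempotent), not arbitrary third-party SBML.
* Boundary metabolites are declared explicitly, never inferred.
* Ordered bi-bi uses the classic five-step Cleland cycle (four intermediates
  plus free enzyme).

## Known limitations

* Uniformity of the Gibbs-energy draw is exact only in loop-free networks;
  looped networks use projection with accept/reject.
* No component-contribution estimation of standard Gibbs energies and no
  pH/ionic-strength corrections: ranges are taken as given.
* No ABC-SMC tolerance schedules, no likelihood-based or gradient fitting.
* Control coefficients are undefined (NaN rows) for zero-flux reactions.
* Mechanism arities require unit stoichiometric coefficients; non-unit
  stoichiometry is supported through mass-action laws only.
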