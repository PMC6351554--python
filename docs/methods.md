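# Methods

## Scope and model structure

`pbutkin` simulates the removal of two prototype protein-bound uremic
toxins — indoxyl sulfate (T₁) and p-cresyl sulfate (T₂) — and one optional
displacer drug (D) during extracorporeal dialysis, at the single-session
and multi-week scales.  The model world contains seven chemical species,
`{T₁, PT₁, T₂, PT₂, D, PD, P}`: each solute free and bound to albumin, plus
free (unoccupied) albumin P.  One binding site per albumin molecule is
modeled (Sudlow site II, shared by IS, pCS, tryptophan, and ibuprofen);
secondary sites, cooperativity, and temperature/pH dependence of the
affinity are out of scope.

Three sub-models are coupled into a single stiff ODE system:

1. **Binding chemistry** (`pbutkin.binding`).  Law of mass action,
   `P + Tᵢ ⇌ PTᵢ`, with a common association rate k₁ = 10⁸ M⁻¹·min⁻¹ for
   all solutes and dissociation rates k₂ = k₁/K_A.  Binding is therefore
   fast (sub-second) relative to transport but is integrated with finite
   kinetics rather than as an algebraic constraint; the implicit integrator
   absorbs the stiffness.  The association constants of the toxins are not
   free parameters: they are calibrated from the initial condition via
   K_A,i = PTᵢ/(Tᵢ·P) with the bound mass of *all* co-resident solutes
   subtracted from total albumin (P = P_tot − ΣPTⱼ).  With the baseline
   initial condition (IS 100 µM at 7% free, pCS 150 µM at 5% free, albumin
   600 µM) this yields K_A ≈ 3.64×10⁴ and 5.21×10⁴ M⁻¹.  The joint
   equilibrium solver reduces the coupled system to a scalar monotone
   equation in P, g(P) = P + Σ totᵢ·Kᵢ·P/(1+Kᵢ·P) − P_tot, bracketed on
   [0, P_tot] and solved with Brent's method — this guarantees the unique
   non-negative root without damping heuristics.

2. **Patient** (`pbutkin.patient`).  Three compartments: plasma (V_pl,
   3.5 L), interstitium (V_is, 12 L), and an intracellular distribution
   volume (V_ic, 28 L, constant during dialysis).  Free solutes exchange
   plasma↔interstitium (K_ip = 1135 mL/min) and
   interstitium↔intracellular (K_ic = 100 mL/min), and are dragged
   convectively interstitium→plasma by ultrafiltration at rate
   α·Q_uf·C_is with α = V_is/(V_pl+V_is); ultrafiltration shrinks V_pl and
   V_is in the same proportion.  Albumin and complexes exist only in plasma
   and interstitium; lymphatic protein return is neglected both during and
   between sessions.  Toxins are generated at constant rates (IS
   0.02477 mg/min, pCS 0.02557 mg/min) into the intracellular pool.  The
   drug is eliminated first-order from plasma **free** drug at rate λ
   (hepatic metabolism; the governing-equation text places λ on the free
   drug, and we follow that placement).  Extracellular species are
   integrated as molar amounts (d(V·C)/dt form) so volume changes commute
   exactly with mass accounting.

3. **Extracorporeal circuit** (`pbutkin.circuit`).  An arterial plug-flow
   tube segment (0.5 m from infusion site to dialyzer inlet) mixes plasma
   with the infusion stream — flow-weighted mixing at the inlet, then pure
   advection plus chemistry; axial diffusion is neglected.  The
   counter-current hollow-fiber dialyzer distributes blood over N = 12300
   fibers; under the uniform-filtration assumption the blood-side flow
   decreases and dialysate flow increases linearly along the fiber.  Free
   small solutes cross the membrane diffusively (KoA = 600 mL/min,
   multiplied by the Péclet correction Pe/(e^Pe−1)) and convectively
   (σ = 0); albumin and complexes cross only convectively with σ = 0.999.
   Ideal membrane adsorption is modeled as the infinite-dialysate-flow
   limit: the free-solute dialysate concentration is pinned at zero and the
   captured mass is accounted from the transmembrane flux integral.  A
   venous tube segment mirrors the arterial one and receives post-dilution
   replacement fluid.  All five modalities share this single topology, so
   HDF with zero replacement fluid is bit-identical to HD by construction.

## Modalities and flows

Plasma flow entering the circuit is Q_pi = Q_b·(1 − Hct) (195 mL/min at
Q_b = 300 mL/min, Hct 0.35) — the standard dialysis-kinetics convention;
the source model does not state the formula explicitly.  The total
filtration along the fiber is J_v = Q_uf + Q_R, where Q_uf is the net
patient fluid removal (2.4 L per 4 h ⇒ 10 mL/min) and Q_R any replacement
or carrier flow that must also be removed (pre-dilution HDF: 20 or 60 L per
session; displacer carrier: 500 or 200 mL per session, removed by raising
the ultrafiltration so net patient fluid loss stays exactly 2.4 L).  The
venous return flow is always Q_pi − Q_uf.  The whole-dialyzer Péclet
number is defined as Pe = J_v·(1−σ)/KoA; the source leaves the exact Pe
definition qualitative, so this choice is exposed in code rather than
buried.

## Displacer pharmacology

Drugs are defined by molecular weight, affinity, dose, carrier volume, and
the clinically reported **total-serum** half-life (tryptophan: K_A
1.73×10⁴ M⁻¹, 2000 mg in 500 mL, t½ 2.83 h; ibuprofen: 1.76×10⁵ M⁻¹,
800 mg in 200 mL, t½ 2 h; molecular weights 204.23 and 206.29 g/mol are
standard values).  Only free drug is metabolized, so the model's free
elimination rate λ must be calibrated: we require that, starting from the
peak with free drug equilibrated across all three pools, total serum drug
concentration halves in exactly the reported half-life.  Two choices are
open here and both are made explicit:

* **Peak amount.**  The reported half-life describes the post-infusion
  decay, whose peak is the drug amount in the patient at the *end of the
  session* — not the full dose, most of which is dialyzed away or
  metabolized during the infusion.  `engine.calibrate_displacer` closes
  this loop self-consistently: calibrate λ at an assumed peak, simulate the
  displacer session, update the peak with the end-of-session residual, and
  iterate (converges in ~3 iterations; the fixed point is insensitive to
  the starting guess).  Because albumin binding is partially saturated at
  these amounts, the calibrated λ does depend on the peak; the
  single-shot calibration with an explicit `dose_mg` is available for
  sensitivity work.
* **Background toxins.**  By default the calibration patient carries no
  circulating toxins (the half-life statement makes no reference to them);
  `with_toxins=True` keeps the baseline toxin load on albumin, which
  lengthens the calibrated free half-life by roughly a third (toxins
  occupy albumin, lowering the drug's bound reservoir).

## Multi-session schedules

Schedules run thrice weekly (2-2-3 day spacing, configurable) over 28 days
(integer weeks give a clean periodic readout; the source's "one month" is
not otherwise specified).  Between sessions the closed patient is
integrated with constant generation, first-order drug washout, and
constant-rate solute-free fluid intake equal to the intra-dialytic removal,
so fluid state is periodic.  At the end of each chained session the
blood-side circuit hold-up (tubes plus fiber lumina, ~0.25 L) is returned
to plasma — the clinical rinse-back.  This matters: each session starts
with a solute-free circuit, and silently discarding the hold-up at session
end would drain about 1.4% of total body albumin per session, visibly
depressing binding capacity and every concentration over a month.  With
rinse-back the conventional-HD month is week-periodic from the first week,
which is also the stated construction of the generation rates (pre-dialysis
concentration repeating week over week under matched fluid balance).

The time-averaged concentration (TAC) integrates total plasma toxin
concentration over the whole horizon (trapezoid on the merged
session/inter-dialytic series) divided by the horizon.  TAC is reported in
µM (and mg/L).  Note a units inconsistency in the published month-scale
figures: the TAC values printed there as "mg/L" are only consistent with
the model's own initial conditions and generation rates on the µM scale
(e.g. an HD TAC of 83.6 can only be µM when the pre-dialysis concentration
is 100 µM = 21.3 mg/L); this package therefore compares month-scale
results on the µM scale.

## Parameters not printed in the source, and their sensitivity

Two parameters of the original study are not recoverable from its text:

* **Interstitial albumin concentration.**  Default 300 µM — 50% of the
  plasma concentration, the textbook interstitial-to-plasma albumin ratio,
  which also places the larger albumin *mass* in the interstitium
  (3.6 vs 2.1 mmol), consistent with the interstitium acting as the larger
  toxin reservoir.  This is the dominant tolerance driver for reproducing
  the session outcome table: more interstitial albumin means a larger
  bound reservoir, which raises net removal but slows the plasma
  reduction ratio and lengthens the calibrated drug free half-life.
  `scripts/sensitivity.py` sweeps this parameter and prints the session
  outcomes and calibrated half-lives across 240-480 µM.
* **Bloodline cross-section.**  Default 1.81×10⁻⁵ m² (4.8 mm inner
  diameter, standard adult bloodline).  It only sets the ~10 s tube
  residence time and is negligible for 4-hour outcomes.

## Numerics

Method of lines with conservative first-order upwind finite volumes:
100 dialyzer nodes and 20 tube nodes by default (the transmembrane terms
are exactly antisymmetric between the two sides, so membrane crossings
conserve mass identically).  The assembled system (patient + quadratures +
four spatial blocks, ~1700 states at defaults) is integrated with scipy's
BDF at rtol 10⁻⁶ / atol 10⁻¹² using a sparse Jacobian pattern (chemistry
couples species within a node; advection couples upwind neighbors;
diffusion couples the two dialyzer sides node-wise).  Removal is accounted
by quadrature states integrated alongside the solution, which makes the
per-toxin session mass balance close to ~10⁻¹⁰ relative and provides an
always-on audit (asserted to 0.1% in the tests).  Upwinding smears the
startup front over a few cells, but session outcomes are grid-converged:
doubling the spatial resolution changes every session metric by well under
0.5% (asserted in tests).  Degenerate inputs are handled explicitly: K_A=0
solutes carry zero rate constants (no 0/0 in the dissociation rate), the
Péclet factor evaluates its removable singularity at 0 via expm1 and clips
to 0 beyond Pe = 700, the log-mean in the clearance metric takes its limit
C₀ at equal endpoints, and infeasible filtration fractions (Q_p(L) ≤ 0)
raise before integration starts.

The model is fully deterministic; the configuration records a seed only as
provenance metadata.

## Validation strategy

Independent oracles back every layer: the equilibrium solver against the
closed-form single-solute quadratic and against relaxation of the kinetic
ODEs; the plug-flow tube against the exact residence-time lag; the
dialyzer against the closed-form counter-current (Michaels) clearance at
zero filtration (within 1% at 200 nodes); the patient model against the
analytic single-pool exponential decay in the unbound, fast-exchange limit
(within 1%); and conservation audits everywhere.  The acceptance tests
then compare the seven-modality session table, the calibrated free
half-lives, residual drug masses, and month-scale TACs against the
published values at the stated tolerances.

## Known limitations

* One albumin binding site; no Sudlow site I toxins or drug cocktails.
* No residual renal function, no OAT-mediated tubular secretion, no
  access/cardiopulmonary recirculation.
* Ideal adsorption is an upper bound (zero dialysate concentration); real
  mixed-matrix membranes have finite capacity and thicker walls.
* The kynurenine pathway is not modeled: infused tryptophan is treated as
  eliminated, not as a source of downstream protein-bound metabolites.
* Uniform filtration along the fiber; no radial concentration
  polarization or boundary-layer correlations.
* Inter-dialytic physiology is reduced to constant generation, constant
  fluid intake, and drug washout; no circadian or dietary variation.
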