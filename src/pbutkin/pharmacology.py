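"""Displacer drugs and free-drug elimination calibration.

A binding competitor (tryptophan or ibuprofen) is infused pre-dialyzer at a
constant rate during the session.  Its clinically reported half-life refers
to *total* serum concentration (free + albumin-bound), but only the free
fraction is metabolized by the liver; the model therefore carries a
first-order elimination rate ``lambda`` acting on plasma *free* drug, and
this module calibrates lambda so that total serum drug concentration halves
in exactly the reported total half-life when the drug is equilibrated
across the three patient pools.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .binding import (
    BOUND_IDX,
    FREE_IDX,
    P_IDX,
    DEFAULT_K_ASSOC,
    BindingSolute,
)
from .patient import PatientParams, PatientState, patient_rhs

__all__ = [
    "DrugSpec",
    "TRYPTOPHAN",
    "IBUPROFEN",
    "drug_binding_solute",
    "infusion_profile",
    "distribute_drug_mass",
    "calibrate_free_elimination",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DrugSpec:
    """A displacer drug prescription.

    ``total_half_life`` is the reported half-life of *total* serum
    concentration (min); ``lambda_free`` (min^-1) is the calibrated
    first-order elimination rate of plasma free drug (None until
    calibrated; the free half-life is ln2 / lambda_free).
    """

    name: str
    mol_weight: float          # g/mol
    K_A: float                 # M^-1
    dose: float                # mg
    carrier_volume: float      # mL
    infusion_duration: float   # min
    total_half_life: float     # min
    lambda_free: float | None = None

    def __post_init__(self) -> None:
        if min(self.dose, self.carrier_volume, self.infusion_duration,
               self.total_half_life, self.mol_weight) <= 0:
            raise ValueError(f"{self.name}: doses, volumes and half-lives must be > 0")
        if self.K_A < 0:
            raise ValueError(f"{self.name}: K_A must be >= 0")

    @property
    def free_half_life(self) -> float:
        if self.lambda_free is None:
            raise ValueError(f"{self.name}: lambda_free not calibrated yet")
        return LN2 / self.lambda_free


#: Tryptophan, 2000 mg in 500 mL saline over a 4 h session; Sudlow II
#: affinity 1.73e4 M^-1, total serum half-life 2.83 h.
TRYPTOPHAN = DrugSpec(
    name="tryptophan", mol_weight=204.23, K_A=1.73e4, dose=2000.0,
    carrier_volume=500.0, infusion_duration=240.0, total_half_life=2.83 * 60.0,
)

#: Ibuprofen, 800 mg in 200 mL saline over a 4 h session; affinity
#: 1.76e5 M^-1, total serum half-life 2 h.
IBUPROFEN = DrugSpec(
    name="ibuprofen", mol_weight=206.29, K_A=1.76e5, dose=800.0,
    carrier_volume=200.0, infusion_duration=240.0, total_half_life=120.0,
)


def drug_binding_solute(drug: DrugSpec, k_assoc: float = DEFAULT_K_ASSOC) -> BindingSolute:
    """The drug as a binding solute (zero initial concentration, no generation)."""
    k2 = k_assoc / drug.K_A if drug.K_A > 0 else 0.0
    return BindingSolute(
        name=drug.name, total_conc_init=0.0, free_fraction_init=1.0,
        K_A=drug.K_A, k_assoc=k_assoc if drug.K_A > 0 else 0.0, k_dissoc=k2,
        generation_rate=0.0, mol_weight=drug.mol_weight,
    )


def infusion_profile(drug: DrugSpec) -> tuple[float, np.ndarray]:
    """Constant-rate infusion stream: (Q_R in mL/min, C_in as 7-species M).

    Only free drug exists in the carrier; Q_R = carrier_volume / duration
    and C_in,D = dose / carrier_volume converted to molar.
    """
    Q_R = drug.carrier_volume / drug.infusion_duration
    C_in = np.zeros(7)
    if drug.dose > 0:
        # mg/mL == g/L; over g/mol gives mol/L
        C_in[FREE_IDX[2]] = (drug.dose / drug.carrier_volume) / drug.mol_weight
    return Q_R, C_in


def _free_protein_given_drug(
    alb_tot: float, toxin_K: np.ndarray, toxin_tot: np.ndarray,
    K_D: float, c_free_drug: float,
) -> float:
    """Free albumin when toxin *totals* are fixed and free drug is prescribed."""
    if alb_tot == 0.0:
        return 0.0

    def g(P):
        occ = float(np.sum(toxin_tot * toxin_K * P / (1.0 + toxin_K * P)))
        return P * (1.0 + K_D * c_free_drug) + occ - alb_tot

    return brentq(g, 0.0, alb_tot, rtol=1e-15)


def distribute_drug_mass(
    dose_mg: float,
    drug: DrugSpec,
    params: PatientParams,
    base: PatientState,
    toxin_solutes: Sequence[BindingSolute] = (),
) -> PatientState:
    """Equilibrate a drug mass across the three pools of a patient state.

    The free drug concentration is taken equal in plasma, interstitium, and
    the intracellular pool (the pre-peak equilibrium assumption); plasma and
    interstitial bound drug follow from local binding equilibria at fixed
    local toxin totals.  The common free concentration is found by scalar
    root-finding on total drug mass.
    """
    K_tox = np.array([s.K_A for s in toxin_solutes])
    tot_pl = np.array([base.pl[FREE_IDX[i]] + base.pl[BOUND_IDX[i]]
                       for i in range(len(toxin_solutes))])
    tot_is = np.array([base.is_[FREE_IDX[i]] + base.is_[BOUND_IDX[i]]
                       for i in range(len(toxin_solutes))])
    mol_target = dose_mg * 1e-3 / drug.mol_weight

    def total_mass(c):
        P_pl = _free_protein_given_drug(params.albumin_pl, K_tox, tot_pl, drug.K_A, c)
        P_is = _free_protein_given_drug(params.albumin_is, K_tox, tot_is, drug.K_A, c)
        mol = c * (base.V_pl + base.V_is + params.V_ic)
        mol += drug.K_A * c * P_pl * base.V_pl + drug.K_A * c * P_is * base.V_is
        return mol

    c_hi = mol_target / params.V_ic  # everything free in the smallest share -> upper bound
    c = brentq(lambda x: total_mass(x) - mol_target, 0.0, c_hi, rtol=1e-13)

    state = base.copy()
    for pool, V, alb, tots in (
        ("pl", base.V_pl, params.albumin_pl, tot_pl),
        ("is_", base.V_is, params.albumin_is, tot_is),
    ):
        P = _free_protein_given_drug(alb, K_tox, tots, drug.K_A, c)
        vec = getattr(state, pool)
        vec[FREE_IDX[2]] = c
        vec[BOUND_IDX[2]] = drug.K_A * c * P
        vec[P_IDX] = P
        # re-partition fixed toxin totals against the new free protein
        for i in range(len(toxin_solutes)):
            free = tots[i] / (1.0 + K_tox[i] * P)
            vec[FREE_IDX[i]] = free
            vec[BOUND_IDX[i]] = tots[i] - free
    state.ic[2] = c
    return state


def _serum_half_time(
    lam: float,
    drug: DrugSpec,
    params: PatientParams,
    y0: np.ndarray,
    serum0: float,
    solutes: Sequence[BindingSolute],
    t_max: float,
) -> float:
    """Time for total serum drug (free + bound, plasma) to reach serum0/2."""

    def rhs(t, y):
        return patient_rhs(y, params, solutes, None, 0.0, lam)

    def halved(t, y):
        V_pl = y[17]
        return (y[FREE_IDX[2]] + y[BOUND_IDX[2]]) / V_pl - 0.5 * serum0

    halved.terminal = True
    halved.direction = -1
    sol = solve_ivp(rhs, (0.0, t_max), y0, method="BDF", rtol=1e-8, atol=1e-14,
                    events=halved)
    if not sol.success:
        raise RuntimeError(f"half-life simulation failed: {sol.message}")
    if sol.t_events[0].size == 0:
        return np.inf
    return float(sol.t_events[0][0])


def calibrate_free_elimination(
    drug: DrugSpec,
    params: PatientParams,
    background_solutes: Sequence[BindingSolute] = (),
    with_toxins: bool = False,
    dose_mg: float | None = None,
    rtol: float = 1e-6,
) -> float:
    """Calibrate the free-drug elimination rate lambda (min^-1).

    Starts from the drug dose equilibrated across the closed three-pool
    patient (peak condition) and root-finds lambda so that total serum drug
    concentration halves in exactly ``drug.total_half_life``.  By default
    the calibration runs without circulating toxins occupying albumin
    (``with_toxins=True`` keeps the baseline toxin load on the protein).

    Returns lambda; the corresponding free half-life is ln2 / lambda.
    """
    from .patient import initialize_patient  # local to avoid cycle at import time

    if with_toxins:
        toxins = list(background_solutes)
    else:
        toxins = [replace(s, total_conc_init=0.0, generation_rate=0.0)
                  for s in background_solutes]
    # strip generation: the calibration patient is at steady state but for the drug
    toxins = [replace(s, generation_rate=0.0) for s in toxins]
    solutes = toxins + [drug_binding_solute(drug)]

    base = initialize_patient(params, toxins)
    state0 = distribute_drug_mass(dose_mg if dose_mg is not None else drug.dose,
                                  drug, params, base, toxins)
    y0 = state0.to_vector()
    serum0 = state0.pl[FREE_IDX[2]] + state0.pl[BOUND_IDX[2]]
    target = drug.total_half_life
    t_max = 20.0 * target

    def objective(lam):
        return _serum_half_time(lam, drug, params, y0, serum0, solutes, t_max) - target

    lo, hi = LN2 / target, 100.0
    f_lo = objective(lo)
    if f_lo < 0:
        # free elimination at the total-serum rate is already too fast
        # (cannot happen when binding shelters the drug, but keep the
        # bracket honest for unbound drugs)
        lo *= 0.01
        f_lo = objective(lo)
    if f_lo < 0 or objective(hi) > 0:
        raise RuntimeError("could not bracket the elimination rate")
    return float(brentq(objective, lo, hi, rtol=rtol))
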