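"""Three-compartment patient model.

Plasma and interstitial pools carry all seven chemical species (free and
albumin-bound toxins/drug plus free albumin); the intracellular pool carries
free solutes only — albumin and its complexes do not exist there.  Free
solutes exchange diffusively between plasma and interstitium (K_ip) and
between interstitium and the intracellular pool (K_ic); ultrafiltration
drags interstitial free solute convectively into plasma while shrinking
both extracellular volumes in proportion alpha = V_is / (V_pl + V_is).
Toxin generation enters the intracellular pool at a constant rate and the
displacer drug is eliminated first-order (rate lambda) from plasma free
drug, representing hepatic metabolism.

State layout (:func:`PatientState.to_vector`, length 19):
``[n_pl(7) mol, n_is(7) mol, c_ic(3) M, V_pl L, V_is L]`` — extracellular
species are carried as molar *amounts* so the balances match the
d(V*C)/dt form of the governing equations exactly; the intracellular pool
has constant volume and is carried as concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .binding import (
    BOUND_IDX,
    FREE_IDX,
    P_IDX,
    BindingSolute,
    mass_action_rates,
    rate_constants,
    solve_competitive_equilibrium,
)

__all__ = [
    "PatientParams",
    "PatientState",
    "CircuitExchange",
    "patient_derivatives",
    "interdialytic_step",
    "initialize_patient",
    "total_toxin_mass",
]

ML_TO_L = 1e-3
N_PATIENT_STATES = 19


@dataclass(frozen=True)
class PatientParams:
    """Patient volumes, transfer coefficients and albumin levels.

    Volumes in L, transfer coefficients in mL/min, albumin in M.
    """

    V_pl0: float = 3.5
    V_is0: float = 12.0
    V_ic: float = 28.0
    hematocrit: float = 0.35
    K_ip: float = 1135.0
    K_ic: float = 100.0
    albumin_pl: float = 600e-6
    albumin_is: float = 300e-6

    def __post_init__(self) -> None:
        if min(self.V_pl0, self.V_is0, self.V_ic) <= 0:
            raise ValueError("all volumes must be > 0")
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must be in (0, 1)")
        if self.K_ip <= 0 or self.K_ic <= 0:
            raise ValueError("transfer coefficients must be > 0")
        if self.albumin_pl < 0 or self.albumin_is < 0:
            raise ValueError("albumin concentrations must be >= 0")

    def plasma_flow(self, Q_b: float) -> float:
        """Plasma flow Q_pi = Q_b * (1 - hematocrit), mL/min."""
        return Q_b * (1.0 - self.hematocrit)


@dataclass
class PatientState:
    """Instantaneous patient state.

    ``pl`` and ``is_`` are 7-species concentration vectors (M); ``ic`` holds
    the three free-solute concentrations (M) of the protein-free
    intracellular pool.
    """

    V_pl: float
    V_is: float
    pl: np.ndarray
    is_: np.ndarray
    ic: np.ndarray

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.pl * self.V_pl, self.is_ * self.V_is, self.ic,
             [self.V_pl, self.V_is]]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "PatientState":
        y = np.asarray(y, dtype=float)
        V_pl, V_is = y[17], y[18]
        if V_pl <= 0 or V_is <= 0:
            raise ValueError(f"non-positive compartment volume: V_pl={V_pl}, V_is={V_is}")
        return cls(V_pl=V_pl, V_is=V_is, pl=y[0:7] / V_pl,
                   is_=y[7:14] / V_is, ic=y[14:17].copy())

    def copy(self) -> "PatientState":
        return PatientState(self.V_pl, self.V_is, self.pl.copy(),
                            self.is_.copy(), self.ic.copy())


@dataclass
class CircuitExchange:
    """What the extracorporeal circuit exchanges with the patient.

    ``Q_pi`` is plasma flow leaving the patient and ``Q_return`` the flow
    returning at venous access (both mL/min); ``returned`` holds the species
    concentrations (M) at the venous return.
    """

    Q_pi: float
    Q_return: float
    returned: np.ndarray


def _generation_mol(solutes: Sequence[BindingSolute]) -> np.ndarray:
    """Generation of (T1, T2, D) in mol/min (mg/min over g/mol is mmol/min)."""
    g = np.zeros(3)
    for i, s in enumerate(solutes):
        g[i] = s.generation_rate / s.mol_weight * 1e-3
    return g


def patient_rhs(
    y: np.ndarray,
    params: PatientParams,
    solutes: Sequence[BindingSolute],
    exchange: CircuitExchange | None,
    Q_uf: float,
    lambda_drug: float,
    fluid_gain_rate: float = 0.0,
) -> np.ndarray:
    """Time derivative of the packed 19-element patient vector.

    ``Q_uf`` (mL/min) is the net patient fluid removal through the circuit;
    ``fluid_gain_rate`` (mL/min) is inter-dialytic solute-free fluid intake.
    Both are partitioned between plasma and interstitium by
    alpha = V_is / (V_pl + V_is).
    """
    V_pl, V_is = y[17], y[18]
    C_pl = y[0:7] / V_pl
    C_is = y[7:14] / V_is
    C_ic = y[14:17]
    k1, k2 = rate_constants(solutes)

    r_pl = mass_action_rates(C_pl, k1, k2)
    r_is = mass_action_rates(C_is, k1, k2)

    alpha = V_is / (V_pl + V_is)
    Q_uf_L = Q_uf * ML_TO_L
    K_ip_L = params.K_ip * ML_TO_L
    K_ic_L = params.K_ic * ML_TO_L

    dn_pl = r_pl * V_pl
    dn_is = r_is * V_is

    # free solutes: diffusive inter-compartment exchange and UF-driven convection
    diff_ip = K_ip_L * (C_is[FREE_IDX] - C_pl[FREE_IDX])
    conv_uf = alpha * Q_uf_L * C_is[FREE_IDX]
    diff_ic = K_ic_L * (C_ic - C_is[FREE_IDX])
    dn_pl[FREE_IDX] += diff_ip + conv_uf
    dn_is[FREE_IDX] += diff_ic - diff_ip - conv_uf

    # hepatic elimination of plasma free drug
    dn_pl[FREE_IDX[2]] -= lambda_drug * C_pl[FREE_IDX[2]] * V_pl

    # extracorporeal circuit coupling
    if exchange is not None:
        Q_pi_L = exchange.Q_pi * ML_TO_L
        Q_ret_L = exchange.Q_return * ML_TO_L
        dn_pl += -Q_pi_L * C_pl + Q_ret_L * exchange.returned

    # intracellular pool: constant volume, generation + diffusion
    G = _generation_mol(solutes)
    dC_ic = (G - K_ic_L * (C_ic - C_is[FREE_IDX])) / params.V_ic

    gain_L = fluid_gain_rate * ML_TO_L
    dV_pl = -(1.0 - alpha) * Q_uf_L + (1.0 - alpha) * gain_L
    dV_is = -alpha * Q_uf_L + alpha * gain_L

    return np.concatenate([dn_pl, dn_is, dC_ic, [dV_pl, dV_is]])


def patient_derivatives(
    state: PatientState,
    exchange: CircuitExchange | None,
    Q_uf: float,
    params: PatientParams,
    solutes: Sequence[BindingSolute],
    lambda_drug: float = 0.0,
) -> np.ndarray:
    """Packed time-derivative of a :class:`PatientState` (see module docstring)."""
    return patient_rhs(state.to_vector(), params, solutes, exchange,
                       Q_uf, lambda_drug)


def interdialytic_step(
    state: PatientState,
    duration: float,
    fluid_intake: float,
    params: PatientParams,
    solutes: Sequence[BindingSolute],
    lambda_drug: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-14,
    t_eval_step: float | None = None,
):
    """Integrate the closed patient over an inter-dialytic interval.

    Constant-rate solute-free fluid intake (``fluid_intake`` L over
    ``duration`` min), constant toxin generation, binding re-equilibration,
    and first-order drug elimination; no extracorporeal exchange.

    Returns ``(final_state, t, series)`` where ``series`` has shape
    (19, len(t)) in packed layout (empty arrays when ``t_eval_step`` is None).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    gain = fluid_intake * 1e3 / duration  # L -> mL/min

    def rhs(t, y):
        return patient_rhs(y, params, solutes, None, 0.0, lambda_drug,
                           fluid_gain_rate=gain)

    t_eval = (np.arange(0.0, duration + 0.5 * t_eval_step, t_eval_step)
              if t_eval_step else None)
    sol = solve_ivp(rhs, (0.0, duration), state.to_vector(), method="BDF",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"inter-dialytic integration failed: {sol.message}")
    final = PatientState.from_vector(sol.y[:, -1])
    if t_eval_step:
        return final, sol.t, sol.y
    return final, np.array([]), np.empty((N_PATIENT_STATES, 0))


def initialize_patient(
    params: PatientParams,
    solutes: Sequence[BindingSolute],
) -> PatientState:
    """Pre-dialysis steady state.

    Free solute concentrations are equal across all three compartments
    (no net diffusive flux); the plasma pool is at joint binding equilibrium
    with the prescribed initial totals and plasma albumin, and the
    interstitial bound species follow from the same free concentrations with
    interstitial albumin:  P_is = albumin_is / (1 + sum_i K_i T_i).
    """
    K = np.array([s.K_A for s in solutes] + [0.0] * (3 - len(solutes)))
    totals = np.array([s.total_conc_init for s in solutes]
                      + [0.0] * (3 - len(solutes)))
    pl = solve_competitive_equilibrium(K, totals, params.albumin_pl)
    free = pl[FREE_IDX]

    is_ = np.zeros(7)
    is_[FREE_IDX] = free
    P_is = params.albumin_is / (1.0 + float(np.dot(K, free)))
    is_[P_IDX] = P_is
    is_[BOUND_IDX] = K * free * P_is

    return PatientState(V_pl=params.V_pl0, V_is=params.V_is0,
                        pl=pl, is_=is_, ic=free.copy())


def total_toxin_mass(
    state: PatientState,
    solute: BindingSolute,
    index: int,
    V_ic: float,
) -> float:
    """Whole-body mass (mg) of solute ``index`` (0=T1, 1=T2, 2=D).

    Sums free + bound amounts over plasma and interstitium plus the free
    intracellular amount (volume ``V_ic``, L), converted to mg via the
    molecular weight.
    """
    f, b = FREE_IDX[index], BOUND_IDX[index]
    mol = (
        (state.pl[f] + state.pl[b]) * state.V_pl
        + (state.is_[f] + state.is_[b]) * state.V_is
        + state.ic[index] * V_ic
    )
    return mol * solute.mol_weight * 1e3
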