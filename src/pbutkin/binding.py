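"""Competitive albumin-binding chemistry.

Two uremic toxins and (optionally) one displacer drug compete for a single
binding site on albumin (Sudlow site II).  Everything downstream of this
module — the patient compartments, the tube segments, and every axial node
of the dialyzer — shares the same mass-action reaction terms defined here:

    P + T_i  <=>  PT_i,     K_A,i = k_assoc,i / k_dissoc,i

The free fraction of a solute at equilibrium is f = 1 / (1 + K_A * P) with
P the *free* (unoccupied) albumin concentration, so any process that lowers
P — dilution, or infusion of a binding competitor — raises the dialyzable
free fraction of every bound solute.

Internal units: molar (M) concentrations and minutes throughout; mg and
g/mol appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SPECIES",
    "FREE_IDX",
    "BOUND_IDX",
    "P_IDX",
    "SoluteDefinition",
    "BindingSolute",
    "SpeciesVector",
    "free_fraction",
    "calibrate_binding",
    "solve_competitive_equilibrium",
    "mass_action_rates",
]

#: Canonical species ordering used by every state vector in the package.
SPECIES = ("T1", "PT1", "T2", "PT2", "D", "PD", "P")
FREE_IDX = np.array([0, 2, 4])   # free toxin 1, free toxin 2, free drug
BOUND_IDX = np.array([1, 3, 5])  # their albumin complexes
P_IDX = 6                        # free (unoccupied) albumin

#: Paper-scheme association rate shared by all solutes (M^-1 min^-1).
DEFAULT_K_ASSOC = 1e8


@dataclass(frozen=True)
class SoluteDefinition:
    """Pre-calibration description of one binding solute.

    Parameters
    ----------
    name:
        Identifier ("IS", "pCS", "tryptophan", ...).
    total_conc_init:
        Initial total (free + bound) plasma concentration, M.
    free_fraction_init:
        Initial free fraction in (0, 1].
    mol_weight:
        Molecular weight, g/mol (for mg <-> mol conversion).
    generation_rate:
        Endogenous generation, mg/min (0 for displacer drugs).
    """

    name: str
    total_conc_init: float
    free_fraction_init: float
    mol_weight: float
    generation_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.free_fraction_init <= 1.0):
            raise ValueError(
                f"{self.name}: free_fraction_init must be in (0, 1], "
                f"got {self.free_fraction_init}"
            )
        if self.total_conc_init < 0 or self.generation_rate < 0:
            raise ValueError(f"{self.name}: concentrations and rates must be >= 0")
        if self.mol_weight <= 0:
            raise ValueError(f"{self.name}: mol_weight must be > 0")


@dataclass(frozen=True)
class BindingSolute:
    """A calibrated binding solute (toxin or displacer)."""

    name: str
    total_conc_init: float      # M
    free_fraction_init: float   # (0, 1]
    K_A: float                  # M^-1
    k_assoc: float              # M^-1 min^-1
    k_dissoc: float             # min^-1
    generation_rate: float      # mg/min
    mol_weight: float           # g/mol

    def __post_init__(self) -> None:
        if min(self.K_A, self.k_assoc, self.k_dissoc,
               self.total_conc_init, self.generation_rate) < 0:
            raise ValueError(f"{self.name}: rates and concentrations must be >= 0")
        if not (0.0 < self.free_fraction_init <= 1.0):
            raise ValueError(f"{self.name}: free_fraction_init must be in (0, 1]")
        if self.k_dissoc > 0:
            ratio = self.k_assoc / self.k_dissoc
            if abs(ratio - self.K_A) > 1e-12 * max(self.K_A, 1.0):
                raise ValueError(
                    f"{self.name}: K_A must equal k_assoc/k_dissoc "
                    f"({self.K_A} vs {ratio})"
                )
        elif self.K_A != 0.0:
            raise ValueError(f"{self.name}: k_dissoc = 0 requires K_A = 0")


@dataclass
class SpeciesVector:
    """Concentrations (M) of the seven chemical species at one location."""

    T1: float = 0.0
    PT1: float = 0.0
    T2: float = 0.0
    PT2: float = 0.0
    D: float = 0.0
    PD: float = 0.0
    P: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.T1, self.PT1, self.T2, self.PT2,
                         self.D, self.PD, self.P])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "SpeciesVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (7,):
            raise ValueError(f"expected 7 species, got shape {a.shape}")
        return cls(*a)

    def total(self, solute_index: int) -> float:
        """Total (free + bound) concentration of solute 0, 1, or 2."""
        a = self.as_array()
        return float(a[FREE_IDX[solute_index]] + a[BOUND_IDX[solute_index]])


def free_fraction(K_A: float, P_free: float) -> float:
    """Equilibrium free fraction f = 1 / (1 + K_A * P_free).

    ``P_free`` is the *free* albumin concentration (M), not total albumin.
    """
    if K_A < 0 or P_free < 0:
        raise ValueError("K_A and P_free must be non-negative")
    return 1.0 / (1.0 + K_A * P_free)


def calibrate_binding(
    solutes: Sequence[SoluteDefinition],
    P_tot: float,
    k_assoc: float = DEFAULT_K_ASSOC,
) -> list[BindingSolute]:
    """Calibrate association constants from initial totals and free fractions.

    At the initial joint equilibrium each solute satisfies
    K_A,i = PT_i / (T_i * P) with T_i = f_i * total_i,
    PT_i = (1 - f_i) * total_i, and P = P_tot - sum_j PT_j:
    the bound mass of *every* co-resident solute is subtracted from total
    albumin.  Dissociation rates follow from the fixed association rate,
    k_dissoc,i = k_assoc / K_A,i.

    Raises
    ------
    ValueError
        If the bound solute mass exceeds the available albumin
        (over-saturated protein, P <= 0).
    """
    if P_tot <= 0:
        raise ValueError("P_tot must be > 0")
    bound = [(1.0 - s.free_fraction_init) * s.total_conc_init for s in solutes]
    P_free = P_tot - sum(bound)
    if P_free <= 0:
        raise ValueError(
            f"infeasible calibration: bound solute mass {sum(bound):.3e} M "
            f"saturates total albumin {P_tot:.3e} M"
        )
    out = []
    for s, PT in zip(solutes, bound):
        T = s.free_fraction_init * s.total_conc_init
        if PT == 0.0 or T == 0.0:
            K_A, k1, k2 = 0.0, 0.0, 0.0
        else:
            K_A = PT / (T * P_free)
            k1 = k_assoc
            k2 = k_assoc / K_A
        out.append(
            BindingSolute(
                name=s.name,
                total_conc_init=s.total_conc_init,
                free_fraction_init=s.free_fraction_init,
                K_A=K_A,
                k_assoc=k1,
                k_dissoc=k2,
                generation_rate=s.generation_rate,
                mol_weight=s.mol_weight,
            )
        )
    return out


def solve_competitive_equilibrium(
    K_As: Sequence[float],
    totals: Sequence[float],
    P_tot: float,
    rtol: float = 1e-14,
) -> np.ndarray:
    """Joint binding equilibrium of up to three solutes on one protein.

    Solves the coupled system PT_i = K_A,i * T_i * P, T_i + PT_i = total_i,
    P + sum_i PT_i = P_tot for the unique non-negative root.  Eliminating
    T_i and PT_i leaves a scalar equation in the free protein P,

        g(P) = P + sum_i total_i * K_i * P / (1 + K_i * P) - P_tot = 0,

    with g strictly increasing on [0, P_tot]; the root is bracketed and
    found by Brent's method.

    Returns
    -------
    numpy.ndarray, shape (7,)
        Species concentrations in canonical :data:`SPECIES` order.  Unused
        solute slots (fewer than 3 solutes supplied) are zero.
    """
    K = np.asarray(K_As, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if K.shape != tot.shape or K.ndim != 1 or K.size > 3:
        raise ValueError("K_As and totals must be matching 1-D arrays of size <= 3")
    if np.any(K < 0) or np.any(tot < 0) or P_tot < 0:
        raise ValueError("all inputs must be non-negative")

    def g(P: float) -> float:
        return P + float(np.sum(tot * K * P / (1.0 + K * P))) - P_tot

    if P_tot == 0.0 or np.all(K * tot == 0.0):
        P = P_tot
    else:
        # g(0) = -P_tot < 0, g(P_tot) >= 0: root bracketed in [0, P_tot].
        P = brentq(g, 0.0, P_tot, xtol=1e-300, rtol=max(rtol, 1e-15))

    free = tot / (1.0 + K * P)
    bound = tot - free
    out = np.zeros(7)
    out[FREE_IDX[: K.size]] = free
    out[BOUND_IDX[: K.size]] = bound
    out[P_IDX] = P
    residual = abs(g(P)) / max(P_tot, 1e-300)
    if residual > 1e-10:
        raise RuntimeError(
            f"equilibrium solver did not converge: relative residual {residual:.3e} "
            f"(P={P:.6e}, P_tot={P_tot:.6e})"
        )
    return out


def rate_constants(solutes: Sequence[BindingSolute]) -> tuple[np.ndarray, np.ndarray]:
    """(k_assoc, k_dissoc) arrays padded to length 3 for the fixed species layout."""
    k1 = np.zeros(3)
    k2 = np.zeros(3)
    for i, s in enumerate(solutes):
        k1[i] = s.k_assoc
        k2[i] = s.k_dissoc
    return k1, k2


def mass_action_rates(C: np.ndarray, k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Law-of-mass-action reaction rates for the 7-species vector.

    Parameters
    ----------
    C:
        Concentrations, shape (7,) or (7, n) for n spatial nodes.
    k1, k2:
        Association (M^-1 min^-1) and dissociation (min^-1) rates, shape (3,).

    Returns
    -------
    Rates dC/dt (M/min), same shape as ``C``.  For each solute i,
    d[T_i]/dt = -k1_i T_i P + k2_i PT_i, the complex gets the opposite sign,
    and free protein collects the sum of the free-solute rates.  First-order
    drug elimination is *not* a chemistry term and lives in the patient model.
    """
    C = np.asarray(C, dtype=float)
    P = C[P_IDX]
    r = np.zeros_like(C)
    shape = (3,) + (1,) * (C.ndim - 1)
    k1 = np.asarray(k1, dtype=float).reshape(shape)
    k2 = np.asarray(k2, dtype=float).reshape(shape)
    free_rate = -k1 * C[FREE_IDX] * P + k2 * C[BOUND_IDX]
    r[FREE_IDX] = free_rate
    r[BOUND_IDX] = -free_rate
    r[P_IDX] = free_rate.sum(axis=0)
    return r
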