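"""Coupled mass-action equilibria for homodimer / heterodimer competition.

The binding scheme is the homodimer-competition model

    A + A  <->  A2      K_D(homo) = [A]^2 / [A2]
    A + B  <->  AB      K_D(het)  = [A][B] / [AB]

where A is the RXRα LBD monomer (self-associating) and B is the Nurr1 LBD
monomer (non-self-associating).  Every downstream stage — ITC simulation and
fitting, lineshape populations, the synthetic panel — reduces to these two
solvers.

Both solvers reduce the coupled system to a single scalar equation in free A,
bracketed on [0, total_A], and solve it with Brent's method, which converges
unconditionally on the bracket.  Homotetramer species are deliberately not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BindingParameters",
    "SpeciesState",
    "solve_homodimer",
    "solve_competition",
    "DEFAULT_KD_HOMO",
    "DEFAULT_DH_HOMO",
]

#: RXRα LBD homodimer dissociation constant, M (dilution-ITC determined).
DEFAULT_KD_HOMO = 1.63e-5
#: RXRα LBD homodimerization association enthalpy, kcal/mol.
DEFAULT_DH_HOMO = -13.10

_XTOL = 1e-30  # absolute bracket tolerance for brentq, M
_RTOL = 8.9e-16  # ~4 * machine epsilon, brentq minimum


@dataclass(frozen=True)
class BindingParameters:
    """Ground-truth or fitted equilibrium constants and enthalpies.

    Parameters
    ----------
    kd_homo : float
        Homodimer dissociation constant [A]^2/[A2], M.
    dh_homo : float
        Homodimer association enthalpy, kcal/mol (negative = exothermic).
    log_kd_het : float
        log10 of the heterodimer dissociation constant [A][B]/[AB], log M.
    dh_het : float
        Heterodimer association enthalpy, kcal/mol.
    temperature : float
        Absolute temperature, K.
    """

    kd_homo: float = DEFAULT_KD_HOMO
    dh_homo: float = DEFAULT_DH_HOMO
    log_kd_het: float = -5.335
    dh_het: float = 2.900
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.kd_homo <= 0:
            raise ValueError(f"kd_homo must be positive, got {self.kd_homo}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not math.isfinite(self.log_kd_het):
            raise ValueError("log_kd_het must be finite")

    @property
    def kd_het(self) -> float:
        """Heterodimer dissociation constant, M."""
        return 10.0 ** self.log_kd_het


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations of all species, M."""

    conc_A: float
    conc_A2: float
    conc_B: float
    conc_AB: float

    @property
    def total_A(self) -> float:
        """Total A in monomer units: A + 2*A2 + AB."""
        return self.conc_A + 2.0 * self.conc_A2 + self.conc_AB

    @property
    def total_B(self) -> float:
        return self.conc_B + self.conc_AB


def solve_homodimer(total_A: float, kd_homo: float) -> SpeciesState:
    """Equilibrium of the pure self-association A + A <-> A2.

    Solves ``2 A^2 / kd + A = total_A`` for free monomer A; the positive
    quadratic root is closed-form, so mass balance is exact to rounding.

    Parameters
    ----------
    total_A : float
        Total A concentration in monomer units, M.
    kd_homo : float
        Homodimer dissociation constant, M.

    Returns
    -------
    SpeciesState
        B fields are zero.
    """
    if total_A < 0:
        raise ValueError(f"total_A must be non-negative, got {total_A}")
    if kd_homo <= 0:
        raise ValueError(f"kd_homo must be positive, got {kd_homo}")
    if total_A == 0.0:
        return SpeciesState(0.0, 0.0, 0.0, 0.0)
    # 2A^2 + kd*A - kd*total = 0; numerically stable positive root
    disc = math.sqrt(kd_homo * kd_homo + 8.0 * kd_homo * total_A)
    conc_A = 2.0 * kd_homo * total_A / (kd_homo + disc)  # == (-kd + disc)/4
    conc_A2 = conc_A * conc_A / kd_homo
    return SpeciesState(conc_A, conc_A2, 0.0, 0.0)


def _competition_species(free_A: float, total_B: float, kd_homo: float, kd_het: float):
    """Closed-form A2, B, AB given free A (inner step of the scalar reduction)."""
    conc_A2 = free_A * free_A / kd_homo
    conc_B = total_B / (1.0 + free_A / kd_het)
    conc_AB = free_A * conc_B / kd_het
    return conc_A2, conc_B, conc_AB


def solve_competition(
    total_A: float, total_B: float, kd_homo: float, kd_het: float
) -> SpeciesState:
    """Equilibrium of the homodimer-vs-heterodimer competition.

    B (the titrant, non-self-associating) competes with A's self-dimerization
    for free A monomer.  Reduction: given free A, the remaining species follow
    in closed form; the A mass balance

        f(A) = A + 2 A^2/kd_homo + A*B(A)/kd_het - total_A

    is strictly increasing on [0, total_A] with f(0) <= 0 <= f(total_A), so
    Brent's method on that bracket finds the unique non-negative root.

    Raises
    ------
    ValueError
        On negative totals or non-positive constants.
    """
    if total_A < 0 or total_B < 0:
        raise ValueError("totals must be non-negative")
    if kd_homo <= 0 or kd_het <= 0:
        raise ValueError("dissociation constants must be positive")
    if total_A == 0.0:
        return SpeciesState(0.0, 0.0, total_B, 0.0)
    if total_B == 0.0:
        hs = solve_homodimer(total_A, kd_homo)
        return hs

    def mass_balance(free_A: float) -> float:
        conc_A2, _, conc_AB = _competition_species(free_A, total_B, kd_homo, kd_het)
        return free_A + 2.0 * conc_A2 + conc_AB - total_A

    free_A = brentq(
        mass_balance, 0.0, total_A, xtol=_XTOL, rtol=_RTOL, maxiter=200, full_output=False
    )
    conc_A2, conc_B, conc_AB = _competition_species(free_A, total_B, kd_homo, kd_het)
    return SpeciesState(free_A, conc_A2, conc_B, conc_AB)
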