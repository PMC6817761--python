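"""Spectral densities, geometric factors, and dipolar transition rates.

The building block is the Torchia-Szabo expression for the spin-lattice
relaxation of a nucleus relaxed by a dipolar vector diffusing freely on a
cone.  For a static orientation, with theta the angle between the cone (C3)
axis and B0, the rate is a linear combination of spectral densities
g(tau, omega) = tau/(1 + omega^2 tau^2) weighted by two sets of geometric
factors:

* ``A1 = sin^2(2*Theta)`` and ``A2 = sin^4(Theta)`` depend only on the cone
  half-angle Theta;
* five polynomials ``B1, B2, B4, B5, B6`` in cos(theta) carry the
  orientation dependence.

Under magic-angle spinning cos(theta) becomes time dependent,

    cos(theta(t)) = sqrt(2/3) sin(beta) cos(w_r t + phi) + sqrt(1/3) cos(beta),

with beta the inclination of the C3 axis from the rotor axis.  Because the
B_k are polynomials in cos^2(theta) and cos^4(theta), rotor-period averaging
reduces to averaging those two moments; a further average over beta (powder)
gives constant B-bar factors and closed-form MAS transition rates.

Each squared dipolar coupling is scaled once by the order parameter S^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants
from .exceptions import InvalidParameterError
from .geometry import FieldConditions, MethylGeometry, MotionState, TransitionRates

__all__ = [
    "spectral_density",
    "dipolar_coupling",
    "BFactors",
    "b_factors",
    "mas_time_averaged_moments",
    "mas_averaged_b_factors",
    "powder_b_factors",
    "transition_rates_from_b",
    "transition_rates_oriented",
    "transition_rates_mas",
    "r1_oriented",
    "r1_single_ch",
    "deuteration_factor",
    "cos_theta_mas",
]

#: Overall prefactor of the Torchia-Szabo rate: 9 * omega_D^2 / 64.
_TS_PREFACTOR = 9.0 / 64.0


def spectral_density(tau: float, omega: float):
    """Lorentzian spectral density g(tau, omega) = tau / (1 + omega^2 tau^2).

    Parameters are the correlation time ``tau`` (s, > 0) and angular
    frequency ``omega`` (rad/s, >= 0); the result has units of seconds and
    satisfies 0 < g <= tau.
    """
    if np.any(np.asarray(tau) <= 0):
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    if np.any(np.asarray(omega) < 0):
        raise InvalidParameterError(f"omega must be >= 0, got {omega}")
    return tau / (1.0 + omega * omega * tau * tau)


def dipolar_coupling(gamma_1: float, gamma_2: float, r_angstrom: float) -> float:
    """Dipolar coupling constant omega_D = (mu0/4pi) gamma1 gamma2 hbar / r^3.

    ``r_angstrom`` is the internuclear distance in Angstrom; the result is an
    angular frequency in rad/s.  For a 1.106 A C-H bond this is about
    2 pi * 22.3 kHz.
    """
    if r_angstrom <= 0:
        raise InvalidParameterError(f"r must be > 0, got {r_angstrom}")
    r = r_angstrom * constants.ANGSTROM
    return constants.MU0_OVER_4PI * gamma_1 * gamma_2 * constants.HBAR / r**3


@dataclass(frozen=True)
class BFactors:
    """The five orientational polynomials B1, B2, B4, B5, B6."""

    b1: float
    b2: float
    b4: float
    b5: float
    b6: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.b1, self.b2, self.b4, self.b5, self.b6)


def _b_from_moments(c2: float, c4: float) -> BFactors:
    """B factors from the (possibly averaged) moments cos^2 and cos^4 theta.

    The polynomials are linear in these two moments, so the same formulas
    serve the static, rotor-averaged and powder-averaged cases.
    """
    return BFactors(
        b1=4.0 * (c2 - c4),
        b2=1.0 - 2.0 * c2 + c4,
        b4=4.0 * c4 - 3.0 * c2 + 1.0,
        b5=1.0 - c4,
        b6=1.0 + 6.0 * c2 + c4,
    )


def b_factors(cos_theta: float) -> BFactors:
    """Orientational polynomials at a static angle theta from B0."""
    if abs(cos_theta) > 1.0:
        raise InvalidParameterError(f"|cos_theta| must be <= 1, got {cos_theta}")
    c2 = cos_theta * cos_theta
    return _b_from_moments(c2, c2 * c2)


def mas_time_averaged_moments(beta_deg: float) -> tuple[float, float]:
    """Rotor-period averages of cos^2(theta(t)) and cos^4(theta(t)).

    ``beta_deg`` is the inclination of the C3 axis from the rotor axis in
    degrees.  The second moment is 1/3 for every beta (the magic-angle
    condition); the fourth is
    (1/9)cos^4(b) + (2/3)sin^2(b)cos^2(b) + (1/6)sin^4(b).
    """
    if not 0.0 <= beta_deg <= 180.0:
        raise InvalidParameterError(f"beta must be in [0, 180] deg, got {beta_deg}")
    b = math.radians(beta_deg)
    c2, s2 = math.cos(b) ** 2, math.sin(b) ** 2
    c4bar = c2 * c2 / 9.0 + (2.0 / 3.0) * s2 * c2 + s2 * s2 / 6.0
    return (1.0 / 3.0, c4bar)


def mas_averaged_b_factors(beta_deg: float) -> BFactors:
    """B factors averaged over one rotor period at inclination beta."""
    c2, c4 = mas_time_averaged_moments(beta_deg)
    return _b_from_moments(c2, c4)


def powder_b_factors() -> BFactors:
    """Powder (sphere) averaged B factors: (8/15, 8/15, 4/5, 4/5, 16/5).

    Equivalent to the sphere moments <cos^2 theta> = 1/3,
    <cos^4 theta> = 1/5 inserted in the B polynomials.
    """
    return BFactors(8.0 / 15.0, 8.0 / 15.0, 4.0 / 5.0, 4.0 / 5.0, 16.0 / 5.0)


def cos_theta_mas(beta_deg: float, phase: float) -> float:
    """Instantaneous cos(theta) under MAS at rotor phase ``phase`` (rad)."""
    b = math.radians(beta_deg)
    return math.sqrt(2.0 / 3.0) * math.sin(b) * math.cos(phase) + math.sqrt(1.0 / 3.0) * math.cos(b)


def _pair_rates(omega_d2: float, theta: float, tau1: float, tau2: float, b: BFactors,
                omega_low: float, omega_mid: float, omega_high: float):
    """W0, W1, W2 for one dipolar pair with cone half-angle ``theta``.

    ``omega_d2`` is the S^2-scaled squared coupling; the three frequencies
    are those of the zero-, single- and double-quantum transitions.
    """
    a1 = math.sin(2.0 * theta) ** 2
    a2 = math.sin(theta) ** 4
    pref = _TS_PREFACTOR * omega_d2
    w0 = pref * (spectral_density(tau1, omega_low) * a1 * b.b1
                 + spectral_density(tau2, omega_low) * a2 * b.b2)
    w1 = pref * (spectral_density(tau1, omega_mid) * a1 * b.b4
                 + spectral_density(tau2, omega_mid) * a2 * b.b5)
    w2 = pref * (spectral_density(tau1, omega_high) * 4.0 * a1 * b.b5
                 + spectral_density(tau2, omega_high) * a2 * b.b6)
    return w0, w1, w2


def transition_rates_from_b(geom: MethylGeometry, field: FieldConditions,
                            motion: MotionState, b: BFactors,
                            provenance: str) -> TransitionRates:
    """Assemble all six transition probabilities from a set of B factors.

    The heteronuclear (I-S) rates use omega_D_IS and Theta_IS at the
    zero/single/double-quantum frequencies |wI - wS|, wS (or wI for the
    proton single-quantum rate) and wI + wS.  The homonuclear (I-I) rates
    reuse the same machinery with omega_D_II, Theta_II and frequencies wI
    and 2 wI.
    """
    wd_is2 = geom.s2 * dipolar_coupling(constants.GAMMA_H, constants.GAMMA_C, geom.r_is) ** 2
    wd_ii2 = geom.s2 * dipolar_coupling(constants.GAMMA_H, constants.GAMMA_H, geom.r_ii) ** 2
    om_i, om_s = field.omega_i, field.omega_s
    w0, w1s, w2 = _pair_rates(wd_is2, geom.theta_is, motion.tau1, motion.tau2, b,
                              om_i - om_s, om_s, om_i + om_s)
    # proton single-quantum rate of the IS pair: same form with omega_I
    _, w1i, _ = _pair_rates(wd_is2, geom.theta_is, motion.tau1, motion.tau2, b,
                            om_i - om_s, om_i, om_i + om_s)
    _, w1_ii, w2_ii = _pair_rates(wd_ii2, geom.theta_ii, motion.tau1, motion.tau2, b,
                                  0.0, om_i, 2.0 * om_i)
    return TransitionRates(w0_is=w0, w1s_is=w1s, w1i_is=w1i, w2_is=w2,
                           w1_ii=w1_ii, w2_ii=w2_ii, provenance=provenance)


def transition_rates_oriented(geom: MethylGeometry, field: FieldConditions,
                              motion: MotionState, beta_deg: float) -> TransitionRates:
    """Rotor-period-averaged transition rates at C3-axis inclination beta."""
    return transition_rates_from_b(geom, field, motion,
                                   mas_averaged_b_factors(beta_deg), "mas-beta-resolved")


def transition_rates_instantaneous(geom: MethylGeometry, field: FieldConditions,
                                   motion: MotionState, cos_theta: float) -> TransitionRates:
    """Transition rates at an instantaneous orientation cos(theta) from B0."""
    return transition_rates_from_b(geom, field, motion,
                                   b_factors(cos_theta), "oriented-at-theta")


def transition_rates_mas(geom: MethylGeometry, field: FieldConditions,
                         motion: MotionState) -> TransitionRates:
    """MAS + powder averaged transition rates in closed form.

    With the powder B-bar constants the Torchia-Szabo prefactors collapse to
    3/40 (W0), 9/80 (W1) and 18/40 (W2):

        W0  = (3 wD^2/40)  [g(t1, wI-wS) sin^2 2T + g(t2, wI-wS) sin^4 T]
        W1S = (9 wD^2/80)  [g(t1, wS)    sin^2 2T + g(t2, wS)    sin^4 T]
        W2  = (18 wD^2/40) [g(t1, wI+wS) sin^2 2T + g(t2, wI+wS) sin^4 T]

    each scaled by S^2.  The homonuclear rates follow by substituting
    omega_D_II, Theta_II = 90 deg, and frequencies wI and 2 wI.
    """
    return transition_rates_from_b(geom, field, motion, powder_b_factors(), "powder-averaged")


def r1_from_rates(rates: TransitionRates) -> float:
    """Single-CH-pair R1 = W0 + 2 W1S + W2 from assembled transition rates."""
    return rates.w0_is + 2.0 * rates.w1s_is + rates.w2_is


def r1_oriented(geom: MethylGeometry, field: FieldConditions,
                motion: MotionState, beta_deg: float) -> float:
    """beta-resolved 13C R1 of a single C-H vector under MAS.

    This is the Torchia-Szabo rate with the rotor-averaged B-bar(beta)
    factors, i.e. the residual relaxation anisotropy that MAS leaves.
    """
    return r1_from_rates(transition_rates_oriented(geom, field, motion, beta_deg))


def r1_single_ch(geom: MethylGeometry, field: FieldConditions, motion: MotionState) -> float:
    """Powder-averaged single-pair R1 (the beta average of `r1_oriented`)."""
    return r1_from_rates(transition_rates_mas(geom, field, motion))


def deuteration_factor() -> float:
    """Rate reduction expected when 1H is replaced by 2H in a C-H coupling.

    gamma_H^2 I_H (I_H + 1) / [gamma_D^2 I_D (I_D + 1)] with I_H = 1/2,
    I_D = 1; about 15.9, i.e. the often-quoted factor of ~16.
    """
    spin_h = constants.SPIN_H * (constants.SPIN_H + 1.0)
    spin_d = constants.SPIN_D * (constants.SPIN_D + 1.0)
    return (constants.GAMMA_H / constants.GAMMA_D) ** 2 * spin_h / spin_d
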