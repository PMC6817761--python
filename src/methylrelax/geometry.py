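"""Domain types: methyl geometry, spectrometer conditions, and motional state.

The relaxation model treats the methyl group as n_I protons (I spins) bonded
to one 13C (S spin), with the C-H vectors diffusing freely on a cone about
the local C3 axis.  The geometry is fixed by the half-angle of that cone
(Theta_IS), the C-H distance, and an order parameter S^2 that scales the
squared dipolar coupling to account for fast librational averaging.

Angles are accepted in degrees at every public interface and converted to
radians internally exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import constants
from .exceptions import InvalidParameterError

__all__ = [
    "MethylGeometry",
    "FieldConditions",
    "MotionState",
    "TransitionRates",
]


@dataclass(frozen=True)
class MethylGeometry:
    """Geometry and spin bookkeeping of a CH3 (or generally XHn) group.

    Parameters
    ----------
    theta_is_deg : float
        Angle between the methyl C3 axis and the C-H internuclear vector,
        degrees.  Default 69.1 deg, the liquid-crystal NMR value.
    r_is : float
        C-H internuclear distance in Angstrom (default 1.106).
    theta_ii_deg : float
        Angle between the C3 axis and the H-H vectors; 90 deg for the three
        protons of a methyl group.
    r_ii : float or None
        H-H distance in Angstrom.  If None it is reconstructed from the cone
        geometry: three protons on a circle of radius ``r_is*sin(theta_is)``
        sit sqrt(3) times that radius apart.
    n_i, n_s : int
        Number of I (1H) and S (13C) spins.
    s2 : float
        Squared order parameter in (0, 1] applied once to every squared
        dipolar coupling.
    """

    theta_is_deg: float = 69.1
    r_is: float = 1.106
    theta_ii_deg: float = 90.0
    r_ii: float | None = None
    n_i: int = 3
    n_s: int = 1
    s2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta_is_deg", "theta_ii_deg"):
            th = getattr(self, name) % 180.0
            if th > 90.0:  # fold onto [0, 90]; the rates depend on sin/cos^2
                th = 180.0 - th
            if not 0.0 < th <= 90.0:
                raise InvalidParameterError(f"{name} must fold into (0, 90], got {getattr(self, name)}")
            object.__setattr__(self, name, th)
        if self.r_is <= 0:
            raise InvalidParameterError(f"r_is must be > 0, got {self.r_is}")
        if self.r_ii is None:
            object.__setattr__(
                self, "r_ii", math.sqrt(3.0) * self.r_is * math.sin(math.radians(self.theta_is_deg))
            )
        if self.r_ii <= 0:
            raise InvalidParameterError(f"r_ii must be > 0, got {self.r_ii}")
        if self.n_i < 1 or self.n_s < 1:
            raise InvalidParameterError("n_i and n_s must both be >= 1")
        if not 0.0 < self.s2 <= 1.0:
            raise InvalidParameterError(f"s2 must be in (0, 1], got {self.s2}")

    @property
    def theta_is(self) -> float:
        """Theta_IS in radians."""
        return math.radians(self.theta_is_deg)

    @property
    def theta_ii(self) -> float:
        """Theta_II in radians."""
        return math.radians(self.theta_ii_deg)

    def with_s2(self, s2: float) -> "MethylGeometry":
        """Copy of this geometry with a different order parameter."""
        return replace(self, s2=s2)


@dataclass(frozen=True)
class FieldConditions:
    """Static field (through the Larmor frequencies) and MAS rate.

    All frequencies are angular (rad/s).  ``omega_i`` is the 1H Larmor
    frequency, ``omega_s`` the 13C one, ``mas_rate`` the rotor frequency.
    """

    omega_i: float
    omega_s: float
    mas_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.omega_i > self.omega_s > 0:
            raise InvalidParameterError(
                f"need omega_i > omega_s > 0, got {self.omega_i}, {self.omega_s}"
            )
        if self.mas_rate < 0:
            raise InvalidParameterError("mas_rate must be >= 0")

    @classmethod
    def from_proton_mhz(cls, h1_frequency_mhz: float = 800.0, mas_khz: float = 19.2) -> "FieldConditions":
        """Build from a spectrometer 1H frequency in MHz and MAS rate in kHz.

        The 13C frequency follows from the gyromagnetic-ratio ratio.
        """
        omega_i = 2.0 * math.pi * h1_frequency_mhz * 1e6
        omega_s = omega_i * constants.GAMMA_C / constants.GAMMA_H
        return cls(omega_i=omega_i, omega_s=omega_s, mas_rate=2.0 * math.pi * mas_khz * 1e3)


@dataclass(frozen=True)
class MotionState:
    """Correlation times of free diffusion about the methyl C3 axis.

    The first and second rotational harmonics decay with correlation times
    tau1 and tau2 = tau1/4 exactly.
    """

    tau1: float
    tau2: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.tau1 > 0:
            raise InvalidParameterError(f"tau1 must be > 0, got {self.tau1}")
        object.__setattr__(self, "tau2", self.tau1 / 4.0)

    @classmethod
    def from_temperature(cls, arrhenius, temperature: float) -> "MotionState":
        """Correlation time at ``temperature`` (K) from Arrhenius parameters."""
        return cls(tau1=arrhenius.tau(temperature))


@dataclass(frozen=True)
class TransitionRates:
    """Dipolar transition probabilities (s^-1) for the I-S and I-I pairs.

    ``provenance`` records which orientational average produced them:
    ``"oriented-at-theta"`` (instantaneous cos(theta)), ``"mas-beta-resolved"``
    (time-averaged over the rotor cycle at inclination beta), or
    ``"powder-averaged"`` (additionally averaged over beta).
    """

    w0_is: float
    w1s_is: float
    w1i_is: float
    w2_is: float
    w1_ii: float
    w2_ii: float
    provenance: str = "powder-averaged"

    def __post_init__(self) -> None:
        for name in ("w0_is", "w1s_is", "w1i_is", "w2_is", "w1_ii", "w2_ii"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
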