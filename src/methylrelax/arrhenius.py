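"""Arrhenius law for the methyl rotational correlation time.

tau_1(T) = tau_0 exp(E_a / R T), with E_a in kcal/mol and
R = 1.9872e-3 kcal mol^-1 K^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import R_GAS_KCAL
from .exceptions import InvalidParameterError

__all__ = ["ArrheniusParams", "tau_from_temperature"]


@dataclass(frozen=True)
class ArrheniusParams:
    """Activation energy (kcal/mol) and prefactor (s) of a thermally
    activated correlation time."""

    ea: float
    tau0: float
    ea_stderr: float | None = None
    tau0_stderr: float | None = None

    def __post_init__(self) -> None:
        if self.ea <= 0:
            raise InvalidParameterError(f"ea must be > 0, got {self.ea}")
        if self.tau0 <= 0:
            raise InvalidParameterError(f"tau0 must be > 0, got {self.tau0}")

    def tau(self, temperature):
        """Correlation time tau_1 at ``temperature`` (K)."""
        t = np.asarray(temperature, dtype=float)
        if np.any(t <= 0):
            raise InvalidParameterError("temperature must be > 0 K")
        out = self.tau0 * np.exp(self.ea / (R_GAS_KCAL * t))
        return float(out) if np.isscalar(temperature) else out


def tau_from_temperature(params: ArrheniusParams, temperature: float) -> float:
    """tau_1 = tau_0 exp(E_a / R T); strictly decreasing in T."""
    return params.tau(temperature)
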