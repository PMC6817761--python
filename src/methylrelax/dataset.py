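"""The in-memory container for saturation-recovery measurements."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = ["RecoveryDataset"]


@dataclass
class RecoveryDataset:
    """(recovery delay, intensity) points for one site at one temperature.

    ``provenance`` records, for synthetic data, the generating parameters and
    seed so any curve can be regenerated bit-for-bit.
    """

    times: np.ndarray
    intensities: np.ndarray
    site: str = "site"
    temperature: float = float("nan")
    noise_sigma: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and intensities must be matching 1-D arrays")
        if len(self.times) < 4:
            raise InvalidParameterError("a recovery dataset needs at least 4 points")
        if np.any(self.times < 0):
            raise InvalidParameterError("recovery delays must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("recovery delays must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns site, temperature_K, time_s, intensity."""
        return pd.DataFrame({
            "site": self.site,
            "temperature_K": self.temperature,
            "time_s": self.times,
            "intensity": self.intensities,
        })
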