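"""Synthetic saturation-recovery data with the statistical structure the
fitting machinery assumes.

Curves follow the multi-exponential recovery form
M(t) = M0 (1 - sum_k alpha_k exp(-lambda_k t)) with additive homoscedastic
Gaussian noise expressed relative to M0.  The generating parameters and seed
are recorded in each dataset's provenance so every curve is reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .arrhenius import ArrheniusParams
from .dataset import RecoveryDataset
from .exceptions import InvalidParameterError
from .geometry import FieldConditions, MethylGeometry, MotionState
from .solomon import RecoverySolution, recovery_solution

__all__ = [
    "generate_recovery_curve",
    "default_sampling_times",
    "generate_temperature_series",
]


def generate_recovery_curve(solution: RecoverySolution, times: Sequence[float],
                            noise_sigma: float = 0.0, seed: int | None = None,
                            site: str = "synthetic",
                            temperature: float = float("nan")) -> RecoveryDataset:
    """Sample a recovery solution on ``times`` with optional Gaussian noise.

    ``noise_sigma`` is the noise standard deviation as a fraction of M0.
    With ``noise_sigma == 0`` the analytic curve is reproduced exactly; for
    saturation recovery (sum of amplitudes = 1) the t = 0 intensity is 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("time grid must not be empty")
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    clean = solution.curve(times)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sigma * solution.m0, size=times.shape)
    return RecoveryDataset(
        times=times, intensities=clean, site=site, temperature=temperature,
        noise_sigma=noise_sigma if noise_sigma > 0 else None,
        provenance={
            "rates": np.asarray(solution.rates).tolist(),
            "amplitudes": np.asarray(solution.amplitudes).tolist(),
            "m0": solution.m0,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )


def default_sampling_times(solution: RecoverySolution, n_points: int = 16) -> np.ndarray:
    """Log-spaced recovery delays spanning [0.01/lambda_fast, 5/lambda_slow].

    This covers both the fast intra-methyl recovery and the slow
    spin-diffusion-limited tail of the curve.
    """
    lam_fast = float(np.max(solution.rates))
    lam_slow = float(np.min(solution.rates[np.abs(solution.amplitudes) > 1e-6]))
    return np.geomspace(0.01 / lam_fast, 5.0 / lam_slow, n_points)


def generate_temperature_series(geom: MethylGeometry, field: FieldConditions,
                                arrhenius: ArrheniusParams,
                                n_b: float = 1.6, sigma: float = 0.9,
                                temperatures: Sequence[float] = (268.0, 233.0, 198.0, 178.0, 149.0),
                                n_points: int = 16, noise_sigma: float = 0.0,
                                seed: int | None = None,
                                site: str = "methyl") -> list[RecoveryDataset]:
    """One synthetic recovery dataset per temperature.

    The forward model maps each temperature to tau_1 through the Arrhenius
    law, assembles the MAS-averaged rate matrix (with the spin-diffusion
    bath when sigma > 0), and samples its recovery solution.  The default
    temperatures are the five-step series of a variable-temperature
    saturation-recovery experiment between 268 K and 149 K.
    """
    seeds = (np.random.SeedSequence(seed).spawn(len(temperatures))
             if seed is not None else [None] * len(temperatures))
    out = []
    for temp, sub in zip(temperatures, seeds):
        motion = MotionState.from_temperature(arrhenius, temp)
        sol = recovery_solution(geom, field, motion, n_b=n_b, sigma=sigma)
        times = default_sampling_times(sol, n_points)
        child = int(sub.generate_state(1)[0] % (2**31)) if sub is not None else None
        ds = generate_recovery_curve(sol, times, noise_sigma=noise_sigma, seed=child,
                                     site=site, temperature=temp)
        ds.provenance.update({
            "tau1": motion.tau1, "n_b": n_b, "sigma": sigma, "s2": geom.s2,
            "ea": arrhenius.ea, "tau0": arrhenius.tau0,
        })
        out.append(ds)
    return out
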