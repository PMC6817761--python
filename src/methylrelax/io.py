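"""Reading and writing recovery tables, result tables and run configs.

Recovery data travel as one flat comma-separated table with a header row and
columns ``site, temperature_K, time_s, intensity``; write -> read round
trips preserve values to full float precision.  Configs are YAML key/value
files whose defaults are the standard experimental conditions of the
800 MHz / 19.2 kHz MAS methyl experiment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .arrhenius import ArrheniusParams
from .dataset import RecoveryDataset
from .exceptions import ParseError
from .geometry import FieldConditions, MethylGeometry

__all__ = [
    "REQUIRED_COLUMNS",
    "read_recovery_table",
    "write_recovery_table",
    "datasets_from_frame",
    "RunConfig",
    "load_config",
]

REQUIRED_COLUMNS = ("site", "temperature_K", "time_s", "intensity")


def datasets_from_frame(frame: pd.DataFrame) -> list[RecoveryDataset]:
    """Split a long table into one RecoveryDataset per (site, temperature)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for (site, temp), grp in frame.groupby(["site", "temperature_K"], sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if (times < 0).any():
            row = int(grp.index[times < 0][0])
            raise ParseError(f"negative recovery delay at row {row}")
        order = times.argsort(kind="stable")
        times_sorted = times[order]
        dup = (pd.Series(times_sorted).diff().iloc[1:] == 0)
        if dup.any():
            row = int(grp.index[order][1:][dup.to_numpy()][0])
            raise ParseError(f"duplicate recovery delay at row {row}")
        out.append(RecoveryDataset(times=times_sorted,
                                   intensities=grp["intensity"].to_numpy(dtype=float)[order],
                                   site=str(site), temperature=float(temp)))
    return out


def read_recovery_table(path: str | Path) -> list[RecoveryDataset]:
    """Read a CSV recovery table, grouped by (site, temperature).

    Raises :class:`ParseError` naming the offending row for missing columns,
    negative or duplicate delays.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    return datasets_from_frame(frame)


def write_recovery_table(datasets: list[RecoveryDataset] | RecoveryDataset,
                         path: str | Path) -> None:
    """Write datasets to the flat CSV format `read_recovery_table` accepts."""
    if isinstance(datasets, RecoveryDataset):
        datasets = [datasets]
    frame = pd.concat([ds.to_frame() for ds in datasets], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Flat configuration for the CLI pipelines.

    Spectrometer/geometry block, relaxation-model block and fit block; every
    default is the standard condition of the variable-temperature methyl
    experiment (800 MHz 1H, 19.2 kHz MAS, Theta = 69.1 deg, r_CH = 1.106 A,
    S^2 = 0.93, n_B = 1.6, sigma = 0.9 1/s, E_a = 3.5 kcal/mol,
    tau_0 = 2.5e-13 s).  ``mas_heating_offset_k`` optionally adds a constant
    to nominal temperatures to account for frictional heating under MAS;
    default 0 (off) for temperature scales that are already calibrated.
    """

    h1_frequency_mhz: float = 800.0
    mas_khz: float = 19.2
    theta_is_deg: float = 69.1
    r_is_angstrom: float = 1.106
    s2: float = 0.93
    n_i: int = 3
    n_s: int = 1
    n_b: float = 1.6
    sigma: float = 0.9
    ea_kcal_mol: float = 3.5
    tau0_s: float = 2.5e-13
    temperatures_k: tuple[float, ...] = (268.0, 233.0, 198.0, 178.0, 149.0)
    n_points: int = 16
    noise_sigma: float = 0.0
    n_components: int = 2
    mas_heating_offset_k: float = 0.0
    seed: int | None = None

    def geometry(self) -> MethylGeometry:
        return MethylGeometry(theta_is_deg=self.theta_is_deg, r_is=self.r_is_angstrom,
                              n_i=self.n_i, n_s=self.n_s, s2=self.s2)

    def field(self) -> FieldConditions:
        return FieldConditions.from_proton_mhz(self.h1_frequency_mhz, self.mas_khz)

    def arrhenius(self) -> ArrheniusParams:
        return ArrheniusParams(ea=self.ea_kcal_mol, tau0=self.tau0_s)

    def corrected_temperatures(self) -> tuple[float, ...]:
        return tuple(t + self.mas_heating_offset_k for t in self.temperatures_k)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["temperatures_k"] = list(d["temperatures_k"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config, apply keyword overrides, validate the values."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParseError(f"config {path} must be a mapping of key: value pairs")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "temperatures_k" in data:
        data["temperatures_k"] = tuple(float(t) for t in data["temperatures_k"])
    cfg = RunConfig(**data)
    cfg.geometry()   # trigger domain validation early
    cfg.field()
    cfg.arrhenius()
    return cfg
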