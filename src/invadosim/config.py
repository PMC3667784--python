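"""YAML configuration for model variants, parameters and regimens.

One config file (YAML) holds four blocks, all optional:

``kinetics``  rate constants and initial concentrations
              (:class:`~invadosim.network.KineticParameters` fields),
``pools``     per-pool ``{M_F0, k_ins, k_int}`` overrides for X and D,
``schedule``  insertion regimen
              (:class:`~invadosim.turnover.InsertionSchedule` fields),
``geometry``  spatial grid block (divisions, extent, n_invadopodia,
              timp2_diffusion).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .network import KineticParameters
from .turnover import InsertionSchedule, PoolConfig, default_pools

__all__ = ["load_config", "save_config", "default_config", "RunConfig"]


@dataclasses.dataclass
class RunConfig:
    kinetics: KineticParameters
    pools: list[PoolConfig]
    schedule: InsertionSchedule
    geometry: dict[str, Any]

    def to_dict(self) -> dict:
        return {
            "kinetics": dataclasses.asdict(self.kinetics),
            "pools": {
                p.pool_id: {"M_F0": p.M_F0, "k_ins": p.k_ins, "k_int": p.k_int}
                for p in self.pools
            },
            "schedule": {
                "mode": self.schedule.mode,
                "interval_mode": self.schedule.interval_mode,
                "amount_mode": self.schedule.amount_mode,
                "PH": dict(self.schedule.PH),
                "freq_fold": self.schedule.freq_fold,
                "conc_fold": self.schedule.conc_fold,
                "seed": self.schedule.seed,
            },
            "geometry": dict(self.geometry),
        }


def default_config() -> RunConfig:
    return RunConfig(
        kinetics=KineticParameters(),
        pools=default_pools(),
        schedule=InsertionSchedule(),
        geometry={
            "divisions": [51, 51, 1],
            "extent_um": [5.0, 5.0, 3.0],
            "n_invadopodia": 1,
            "timp2_diffusion": 2e-11,
        },
    )


def load_config(path: str | Path | None) -> RunConfig:
    cfg = default_config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "kinetics" in raw:
        known = {f.name for f in dataclasses.fields(KineticParameters)}
        unknown = set(raw["kinetics"]) - known
        if unknown:
            raise KeyError(f"unknown kinetics keys: {sorted(unknown)}")
        cfg.kinetics = dataclasses.replace(cfg.kinetics, **raw["kinetics"])
    if "pools" in raw:
        pools = []
        for p in cfg.pools:
            upd = raw["pools"].get(p.pool_id, {})
            pools.append(dataclasses.replace(p, **upd))
        cfg.pools = pools
    if "schedule" in raw:
        cfg.schedule = dataclasses.replace(cfg.schedule, **raw["schedule"])
    if "geometry" in raw:
        cfg.geometry.update(raw["geometry"])
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
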