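"""YAML configuration I/O for shift parameters and network configs."""

from __future__ import annotations

from pathlib import Path

import yaml

from .analytics import ShiftParameters
from .des import NetworkConfig, ServiceDistribution, StationConfig
from .errors import ConfigError

__all__ = [
    "load_shift_parameters",
    "load_network_config",
    "dump_network_config",
]


def load_shift_parameters(path) -> ShiftParameters:
    data = yaml.safe_load(Path(path).read_text())
    try:
        return ShiftParameters(
            label=str(data.get("label", "shift")),
            lam=float(data["lam"]),
            mu=float(data["mu"]),
            s=int(data["s"]),
            shift_minutes=float(data.get("shift_minutes", 240.0)),
        )
    except KeyError as exc:
        raise ConfigError(f"shift config missing key {exc}") from exc


def load_network_config(path) -> NetworkConfig:
    data = yaml.safe_load(Path(path).read_text())
    try:
        stations = tuple(
            StationConfig(
                name=str(st["name"]),
                servers=int(st["servers"]),
                service=ServiceDistribution(
                    family=str(st.get("service", {}).get("family", "exponential")),
                    mean_minutes=float(st["service"]["mean_minutes"]),
                ),
            )
            for st in data["stations"]
        )
        return NetworkConfig(
            stations=stations,
            arrival_rate_per_min=float(data["arrival_rate_per_min"]),
            horizon_minutes=float(data["horizon_minutes"]),
            warmup_minutes=float(data.get("warmup_minutes", 0.0)),
            seed=int(data.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid network config: {exc}") from exc


def dump_network_config(config: NetworkConfig, path) -> None:
    data = {
        "arrival_rate_per_min": config.arrival_rate_per_min,
        "horizon_minutes": config.horizon_minutes,
        "warmup_minutes": config.warmup_minutes,
        "seed": config.seed,
        "stations": [
            {
                "name": st.name,
                "servers": st.servers,
                "service": {
                    "family": st.service.family,
                    "mean_minutes": st.service.mean_minutes,
                },
            }
            for st in config.stations
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
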