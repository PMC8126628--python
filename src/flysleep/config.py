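"""YAML configuration round-trip for simulation runs."""

from __future__ import annotations

from pathlib import Path

import yaml

from .sim_engine import SimulationConfig

__all__ = ["load_config", "save_config"]


def load_config(path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML file.

    Sections: ``membrane:``, ``circadian:`` and ``network:`` plus top-level
    engine settings; omitted keys fall back to the package defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path) -> None:
    """Write the fully resolved configuration (all defaults expanded)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
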