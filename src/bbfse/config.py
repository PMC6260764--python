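"""YAML experiment configuration mirroring the healthy-subject protocol card."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .epg import TissueParams
from .sequence import (
    DEFAULT_DK,
    ProtocolCard,
    SequenceTiming,
    default_protocol_card,
    default_timing,
)

__all__ = ["ExperimentConfig", "load_config", "DEFAULT_TISSUES"]

DEFAULT_TISSUES = {
    "wall": {"t1": 880.0, "t2": 40.0},
    "blood": {"t1": 1600.0, "t2": 250.0},
}


@dataclass
class ExperimentConfig:
    """Resolved experiment configuration; defaults encode the healthy-subject protocol."""

    timing: SequenceTiming
    card: ProtocolCard
    tissues: dict[str, TissueParams]
    velocity_grid: np.ndarray
    seed: int = 0
    target_level: float | str = "auto"
    rr_ms: float = 1000.0
    nav_efficiency: float = 1.0

    @classmethod
    def default(cls, seed: int = 0) -> "ExperimentConfig":
        return cls(
            timing=default_timing(),
            card=default_protocol_card(),
            tissues={k: TissueParams(label=k, **v) for k, v in DEFAULT_TISSUES.items()},
            velocity_grid=np.arange(0.0, 101.0, 1.0),
            seed=seed,
        )


def load_config(path: str | Path | None, seed: int | None = None) -> ExperimentConfig:
    """Build a config from a YAML file (missing keys fall back to the defaults).

    Recognised top-level keys: ``timing`` (esp2, n_startup, n_acquired,
    te_eff, dk, acq_window), ``protocol`` (ProtocolCard fields), ``tissues``
    (name -> {t1, t2}), ``velocity_grid`` ({start, stop, step} or a list),
    ``seed``, ``target_level``, ``rr_ms``, ``nav_efficiency``.
    """
    cfg = ExperimentConfig.default()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "timing" in raw:
            t = dict(
                esp2=cfg.timing.esp2,
                n_startup=cfg.timing.n_startup,
                n_acquired=cfg.timing.n_acquired,
                te_eff=cfg.timing.esp1 + cfg.timing.n_startup * cfg.timing.esp2,
                dk=cfg.timing.dk,
                acq_window=cfg.timing.acq_window,
            )
            t.update(raw["timing"])
            cfg.timing = default_timing(**t)
        if "protocol" in raw:
            base = default_protocol_card().__dict__ | raw["protocol"]
            for key in ("fov", "voxel"):
                base[key] = tuple(base[key])
            cfg.card = ProtocolCard(**base)
        if "tissues" in raw:
            cfg.tissues = {
                k: TissueParams(label=k, **v) for k, v in raw["tissues"].items()
            }
        if "velocity_grid" in raw:
            g = raw["velocity_grid"]
            if isinstance(g, dict):
                cfg.velocity_grid = np.arange(
                    g.get("start", 0.0), g.get("stop", 100.0) + g.get("step", 1.0) / 2,
                    g.get("step", 1.0),
                )
            else:
                cfg.velocity_grid = np.asarray(g, dtype=float)
        for key in ("seed", "target_level", "rr_ms", "nav_efficiency"):
            if key in raw:
                setattr(cfg, key, raw[key])
    if seed is not None:
        cfg.seed = seed
    return cfg
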