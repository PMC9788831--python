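"""Pipeline configuration and deterministic per-stage seeding."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic sub-seed for a named pipeline stage (below 2**31)."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Parameters of the desk-scale pipeline, one block per stage."""

    seed: int = 0
    lattice: dict = field(default_factory=lambda: {
        "N": 13, "S": 3, "monomer_rise": 4.0, "inter_pf_spacing": 5.0,
        "length": 320.0, "seams": [0],
    })
    growth: dict = field(default_factory=lambda: {
        "target_length": 2000.0, "p_lat": 0.02, "q_flip": 0.5,
    })
    render: dict = field(default_factory=lambda: {
        "voxel_size": 0.8, "monomer_sigma": 1.6, "decoration_sigma": 1.8,
        "decoration_offset": 4.5, "decoration_amplitude": 0.8,
    })
    wedge: dict = field(default_factory=lambda: {
        "tilt_range": 60.0, "mode": "single", "snr": 3.0,
    })
    sta: dict = field(default_factory=lambda: {
        "spacing": 8.0, "box": 48, "rot_limit": 10.0, "shift_limit": 2.0,
        "iterations": 1, "n_segments": 4,
    })
    caller: dict = field(default_factory=lambda: {
        "s_candidates": [2, 3, 4], "coherence_threshold": 0.3,
        "tolerance": 1.0,
    })
    stats: dict = field(default_factory=lambda: {"segment_length": 160.0})

    def to_yaml(self, path=None) -> str:
        doc = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config block: {key}")
            if isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
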