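"""Run configuration: every tunable of the pipeline with its default value.

Defaults are the method's operating constants: 4.5 Å contact cutoff for
labeling and harvesting, 50%/10% confidence thresholds for patch seeds and
members, 5 Å member radius, 10 Å seed-merge distance, 30% residue-surface
fraction, 4 Å top-1 success distance, BDT d0 = 5 Å, and the PDM grid /
network hyper-parameters.  A config serializes into every run manifest so
any output table can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .features import PdmParams
from .predictor import PredictorConfig

__all__ = ["RunConfig", "manifest"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    # contact & labeling
    contact_cutoff: float = 4.5       # Å, ligand-contact / harvest cutoff
    vdw_tolerance: float = 0.5        # Å, vdW actual-site definition
    # patch assembly
    seed_confidence: float = 0.50     # seeds: confidence strictly above
    member_confidence: float = 0.10   # members: confidence strictly above
    member_radius: float = 5.0        # Å around seeds (inclusive)
    merge_distance: float = 10.0      # Å, seed pairs strictly below merge
    residue_fraction: float = 0.30    # residue positive: strictly above
    success_distance: float = 4.0     # Å, top-1 success criterion
    bdt_d0: float = 5.0               # Å, BDT distance scale
    # surface
    probe_radius: float = 1.4         # Å, solvent probe for SASA
    sasa_points: int = 960
    # geometry attribute
    geometry_radius: float = 10.0     # Å sphere for the free-volume fraction
    geometry_spacing: float = 0.5     # Å sample lattice
    # nested parameter blocks
    pdm: PdmParams = field(default_factory=PdmParams)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "pdm" in d and isinstance(d["pdm"], dict):
            d["pdm"] = PdmParams(**d["pdm"])
        if "predictor" in d and isinstance(d["predictor"], dict):
            d["predictor"] = PredictorConfig(**d["predictor"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def manifest(config: RunConfig, command: str, inputs: dict[str, str],
             outputs: list[str]) -> dict:
    """Run manifest: command, config (+hash), seed and input checksums."""
    import pdmsite

    return {
        "command": command,
        "package_version": getattr(pdmsite, "__version__", "0"),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "inputs": inputs,
        "outputs": outputs,
    }


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
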