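"""Run configuration: one serializable object tying all settings together.

A :class:`RunConfig` collects the model spec, basis, posterior constants,
sampler settings and reference-generation settings, round-trips through
YAML, and hashes canonically so every artifact can be stamped with the
exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .basis import CRBFBasis
from .bayes import BayesConfig
from .elbow import ElbowModelSpec, default_elbow_spec
from .sampler import SamplerConfig

__all__ = ["RunConfig", "config_hash"]


def config_hash(d: dict) -> str:
    """Short stable hash of a JSON-serializable configuration dict."""
    payload = json.dumps(d, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    model: ElbowModelSpec
    basis: CRBFBasis
    bayes: BayesConfig
    sampler: SamplerConfig
    seed: int = 0
    noise_sd: float = 0.01
    cutoff_hz: float = 15.0
    subsample_per_chain: int = 25

    @classmethod
    def default(cls, seed: int = 0, n_iter: int = 200_000,
                n_chains: int = 6) -> "RunConfig":
        """The scaled-down default run geometry."""
        model = default_elbow_spec()
        bayes = BayesConfig()
        basis = CRBFBasis.default(t_f=bayes.t_f)
        dim = model.n_muscles * basis.n_nodes
        sampler = SamplerConfig(dim=dim, n_iter=n_iter, n_chains=n_chains,
                                seed=seed)
        return cls(model=model, basis=basis, bayes=bayes, sampler=sampler,
                   seed=seed)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "basis": self.basis.to_dict(),
            "bayes": self.bayes.to_dict(),
            "sampler": self.sampler.to_dict(),
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "cutoff_hz": self.cutoff_hz,
            "subsample_per_chain": self.subsample_per_chain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sampler_kwargs = dict(d["sampler"])
        return cls(
            model=ElbowModelSpec.from_dict(d["model"]),
            basis=CRBFBasis.from_dict(d["basis"]),
            bayes=BayesConfig(**d["bayes"]),
            sampler=SamplerConfig(**sampler_kwargs),
            seed=int(d.get("seed", 0)),
            noise_sd=float(d.get("noise_sd", 0.01)),
            cutoff_hz=float(d.get("cutoff_hz", 15.0)),
            subsample_per_chain=int(d.get("subsample_per_chain", 25)),
        )

    def hash(self) -> str:
        return config_hash(self.to_dict())

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
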