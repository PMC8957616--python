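"""Pipeline configuration: one flat, validated record of every knob.

Defaults are the analysis defaults throughout the package: 0.01% mean
relative abundance and 37% prevalence filters, CLR pseudocount 1, a
20-point lambda path down to 0.01 x lambda_max, StARS at threshold 0.05
with 50 subsamples of 80%, OR symmetrization, pinned-lambda single-sample
networks, 1000-replicate 80% bootstrap, and a static
betweenness-then-degree attack scored on the largest-component fraction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # taxon filtering
    rel_abund_min: float = 1e-4
    prevalence_min: float = 0.37
    abundance_stat: str = "mean"
    # rarefaction (off by default for network inference)
    rarefy_enabled: bool = False
    rarefaction_depth: int = 50_000
    # CLR
    pseudocount: float = 1.0
    # lambda path + StARS
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_threshold: float = 0.05
    n_subsamples: int = 50
    subsample_fraction: float = 0.8
    symmetrization: str = "OR"
    # single-sample (leave-one-out) networks
    mni_lambda_mode: str = "pinned"  # or "free"
    # bootstrap ensemble
    bootstrap_n: int = 1000
    bootstrap_fraction: float = 0.8
    bootstrap_lambda_mode: str = "pinned"  # or "free"
    # attack simulation
    attack_ordering: str = "betweenness_then_degree"
    attack_response: str = "lcc_fraction"
    # reproducibility / output
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _in01(name, v):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

        _in01("rel_abund_min", self.rel_abund_min)
        _in01("prevalence_min", self.prevalence_min)
        if self.abundance_stat not in ("mean", "max"):
            raise ValueError("abundance_stat must be 'mean' or 'max'")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if not 0 < self.stars_threshold <= 0.5:
            raise ValueError("stars_threshold must be in (0, 0.5]")
        if self.n_subsamples < 2:
            raise ValueError("n_subsamples must be >= 2")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.symmetrization not in ("OR", "AND"):
            raise ValueError("symmetrization must be 'OR' or 'AND'")
        if self.mni_lambda_mode not in ("pinned", "free"):
            raise ValueError("mni_lambda_mode must be 'pinned' or 'free'")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.bootstrap_lambda_mode not in ("pinned", "free"):
            raise ValueError("bootstrap_lambda_mode must be 'pinned' or 'free'")
        if self.attack_ordering not in (
            "betweenness",
            "degree",
            "betweenness_then_degree",
        ):
            raise ValueError(f"unknown attack_ordering {self.attack_ordering!r}")
        if self.attack_response not in ("natural_connectivity", "lcc_fraction"):
            raise ValueError(f"unknown attack_response {self.attack_response!r}")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
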