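"""Configuration objects for simulation and pipeline runs.

Defaults encode the study conditions of the analysis this package reproduces:
a Holstein-style sire population with 38 sequenced sire-son duos, a
rare-heavy site-frequency spectrum (~35% of sites below MAF 0.01), variance
shares of a production trait partitioned as common 83% / rare 3% /
pedigree-only 14% of the additive variance, narrow-sense heritability 0.34,
and per-genotype false-heterozygote rates within the 0.5-2.5% substitution
error range of short-read sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic population generator.

    variance_shares are fractions of the *additive* (genetic) variance
    assigned to causal variants in each MAF class; ``untyped_polygenic`` is
    realized by causal sites that are hidden from the returned genotype
    table, so only pedigree can recover it.
    """

    n_founders: int = 250
    n_generations: int = 3
    n_sires_per_gen: int = 19
    n_sons_per_sire: int = 2
    n_variants: int = 8000
    maf_spectrum: dict = field(
        default_factory=lambda: {"shape": "neutral", "params": {}}
    )
    variance_shares: dict = field(
        default_factory=lambda: {
            "common": 0.83,
            "uncommon": 0.0,
            "rare": 0.03,
            "untyped_polygenic": 0.14,
        }
    )
    h2: float = 0.34
    phenotypic_variance: float = 100.0
    n_causal_per_class: int = 100
    weight_distribution: dict = field(
        default_factory=lambda: {"shape": 2.0, "scale": 2.0, "min": 1.0}
    )
    error_rate: float = 0.02
    n_spurious_sites: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "n_sires_per_gen",
                     "n_sons_per_sire", "n_variants"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        total = sum(self.variance_shares.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"variance_shares must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.variance_shares.values()):
            raise ConfigurationError("variance_shares must be non-negative")
        if not (0.0 < self.h2 <= 1.0):
            raise ConfigurationError("h2 must be in (0, 1]")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ConfigurationError("error_rate must be in [0, 1]")
        if self.n_spurious_sites < 0:
            raise ConfigurationError("n_spurious_sites must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see ``rareherit.pipeline``)."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: dict = field(default_factory=dict)          # QCThresholds overrides
    duo: dict = field(default_factory=lambda: {
        "span": 0.2, "n_bins": 25, "n_replicates": 50, "strict_het": False,
    })
    prediction: dict = field(default_factory=lambda: {"validation_fraction": 0.15})
    seed: int = 0
    out_dir: str = "rareherit_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
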