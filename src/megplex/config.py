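"""Pipeline configuration: fixed analysis constants and their defaults.

Defaults encode the analysis protocol: 4096-sample epochs, the first 60
epochs per recording, six frequency bands, unitary interlayer weight,
mean replica aggregation with max normalization, backward-elimination
removal at p >= 0.10, alpha 0.05 Bonferroni-corrected over 3 tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .spectral import DEFAULT_BANDS, BandDefinition
from .stats import CovariateSpec

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    fs_hz: float = 1250.0
    epoch_length: int = 4096
    max_epochs: int = 60
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    interlayer_weight: float = 1.0
    aggregation: str = "mean"
    normalization: str = "max"
    elimination_threshold: float = 0.10
    alpha: float = 0.05
    m_tests: int = 3
    subnet_file: str | None = None
    seed: int = 0
    ef_tests: list[str] = field(default_factory=lambda: [
        "ef_set_shifting", "ef_word_fluency", "ef_inhibition"
    ])
    covariates: list[CovariateSpec] = field(default_factory=list)
    forced_covariates: list[str] = field(default_factory=list)
    candidate_covariates: list[str] = field(default_factory=list)

    def covariate_specs(self) -> dict[str, CovariateSpec]:
        return {c.name: c for c in self.covariates}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [
            {"name": b.name, "f_lo": b.f_lo, "f_hi": b.f_hi} for b in self.bands
        ]
        d["covariates"] = [
            {"name": c.name, "kind": c.kind, "reference": c.reference}
            for c in self.covariates
        ]
        return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a config from a YAML file; missing keys keep their defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    simple_keys = (
        "fs_hz", "epoch_length", "max_epochs", "interlayer_weight",
        "aggregation", "normalization", "elimination_threshold", "alpha",
        "m_tests", "subnet_file", "seed", "ef_tests",
        "forced_covariates", "candidate_covariates",
    )
    for key in simple_keys:
        if key in raw:
            kwargs[key] = raw[key]
    if "bands" in raw:
        kwargs["bands"] = tuple(
            BandDefinition(b["name"], float(b["f_lo"]), float(b["f_hi"]))
            for b in raw["bands"]
        )
    if "covariates" in raw:
        kwargs["covariates"] = [
            CovariateSpec(c["name"], c["kind"], c.get("reference"))
            for c in raw["covariates"]
        ]
    unknown = set(raw) - set(simple_keys) - {"bands", "covariates"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**kwargs)
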