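"""Run configuration for the end-to-end pipeline (YAML or JSON).

Numeric defaults are the pipeline's standard study conditions: phi step
0.001, bins of 20 nodes, noise variance 0.01, confusion step 0.005.
Unknown keys are rejected with a message naming them.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSpec(_Strict):
    kind: str = "lattice"  # lattice | powerlaw | edgelist
    size: int = 32  # L for lattice, N for powerlaw
    gamma: float = 3.1
    kmin: int = 2
    path: str | None = None  # for kind=edgelist


class PercolationSpec(_Strict):
    dphi: float = Field(0.001, gt=0, lt=1)
    runs: int = Field(100, ge=1)
    mode: str = "coupled"


class SamplingSpec(_Strict):
    bin_size: int = Field(20, ge=1)
    mode: str = "layers"  # layers | random
    n_random_bins: int = 50


class ClusteringSpec(_Strict):
    sigma2: float = Field(0.01, ge=0)
    perplexity: float = 30.0


class ConfusionSpec(_Strict):
    delta: float = Field(0.005, gt=0, lt=1)
    hidden_units: int = 128
    dropout_p: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    test_fraction: float = 0.2


class RunConfig(_Strict):
    network: NetworkSpec = NetworkSpec()
    percolation: PercolationSpec = PercolationSpec()
    sampling: SamplingSpec = SamplingSpec()
    clustering: ClusteringSpec = ClusteringSpec()
    confusion: ConfusionSpec = ConfusionSpec()
    seed: int = 0
    outdir: str = "percolearn-out"


class ConfigError(ValueError):
    pass


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON config file, filling defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        raise ConfigError(f"{path}: empty config")
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        unknown = [
            ".".join(str(p) for p in err["loc"])
            for err in exc.errors()
            if err["type"] == "extra_forbidden"
        ]
        if unknown:
            raise ConfigError(
                f"{path}: unknown config key(s): {', '.join(unknown)}"
            ) from exc
        raise ConfigError(f"{path}: {exc}") from exc
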