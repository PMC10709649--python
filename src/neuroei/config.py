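"""YAML configuration loading.

A single YAML file can hold one block per stage; each block maps directly
onto the corresponding dataclass:

```yaml
idft:
  slope: 1.5
  f0: 1.0
  duration: 5.0
network:
  n_exc: 1000
  n_inh: 250
  g_scale: 2.0
  thalamic_ou: {mean: 0.0, sigma: 400.0, tau: 5.0}
  cortical_poisson: {rate_hz: 3000.0}
```

Unknown keys are rejected, so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .idft import PhaseSpec, SpectralSpec
from .network import (
    NetworkConfig,
    NeuronParams,
    OUParams,
    PoissonParams,
    SynapseParams,
)

__all__ = ["load_config", "spectral_spec_from", "network_config_from"]

_NESTED = {
    "exc_neuron": NeuronParams,
    "inh_neuron": NeuronParams,
    "exc_syn": SynapseParams,
    "inh_syn": SynapseParams,
    "thalamic_ou": OUParams,
    "cortical_poisson": PoissonParams,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a YAML file into a plain dict of stage blocks."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping of stage blocks")
    return data


def spectral_spec_from(block: dict[str, Any]) -> SpectralSpec:
    """Build a SpectralSpec from an ``idft:`` block (phase keys split off)."""
    block = dict(block)
    block.pop("phase", None)
    return SpectralSpec(**block)


def phase_spec_from(block: dict[str, Any]) -> PhaseSpec:
    return PhaseSpec(**(block.get("phase") or {}))


def network_config_from(block: dict[str, Any]) -> NetworkConfig:
    """Build a NetworkConfig from a ``network:`` block, with nested
    neuron/synapse/drive sub-blocks."""
    kwargs: dict[str, Any] = {}
    for key, value in block.items():
        if key in _NESTED:
            kwargs[key] = _NESTED[key](**value)
        else:
            kwargs[key] = value
    return NetworkConfig(**kwargs)
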