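"""Load pipeline configuration from YAML or JSON files.

The file maps directly onto :class:`~phasepower.pipeline.PipelineConfig`,
with nested ``gen`` (generator), ``preproc`` and ``welch`` sections and an
optional ``evoked_kernel`` block inside ``gen``::

    gen:
      n_datasets: 16
      n_trials: 100
      seed: 7
      gain_power_interaction: 0.3
      evoked_kernel: {peak_uv: 5.0}
    preproc:
      baseline_span: [-500, -200]
    bands: [theta, alpha, beta]
    include_phase: true
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .pipeline import PipelineConfig
from .preprocess import PreprocConfig
from .spectral import WelchConfig
from .synth import EvokedKernel, GenConfig

__all__ = ["load_config"]

_TUPLE_FIELDS = {"epoch_span", "artifact_span", "baseline_span", "bands"}


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
            for k, v in d.items()}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML (or JSON) config file into a :class:`PipelineConfig`."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    raw = dict(raw)
    kwargs: dict = {}
    gen = _tuplify(raw.pop("gen", {}))
    if "evoked_kernel" in gen:
        kern = gen.pop("evoked_kernel")
        gen["evoked_kernel"] = EvokedKernel(**kern) if isinstance(kern, dict) else kern
    kwargs["gen"] = GenConfig(**gen)
    kwargs["preproc"] = PreprocConfig(**_tuplify(raw.pop("preproc", {})))
    kwargs["welch"] = WelchConfig(**raw.pop("welch", {}))
    kwargs.update(_tuplify(raw))
    return PipelineConfig(**kwargs)
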