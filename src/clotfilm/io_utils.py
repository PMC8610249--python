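"""Run manifests: provenance for every pipeline stage.

A manifest records the seed, a hash of the resolved configuration and
parameter set, the package version, timestamps and the files a stage
wrote, so a rerun with identical inputs can be checked for identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

from .parameters import ModelConfig, ParameterSet

__all__ = ["config_hash", "write_manifest"]


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)


def config_hash(config: ModelConfig, params: ParameterSet) -> str:
    payload = {
        "config": dataclasses.asdict(config),
        "parameters": params.to_dict(),
    }
    return hashlib.sha256(_canonical_json(payload).encode()).hexdigest()


def write_manifest(
    path: str | Path,
    stage: str,
    config: ModelConfig,
    params: ParameterSet,
    seed: int | None,
    outputs: list[str | Path],
    failures: list | None = None,
    extra: dict | None = None,
) -> Path:
    from . import __version__

    path = Path(path)
    missing = [str(p) for p in outputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing outputs: {missing}")
    manifest = {
        "stage": stage,
        "tool": "clotfilm",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config_hash": config_hash(config, params),
        "outputs": [str(p) for p in outputs],
        "failures": failures or [],
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2))
    return path
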