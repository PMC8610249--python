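"""Reproducible generation of variant vectors for the sensitivity studies.

Two designs are used:

* a Monte Carlo sample of independent multipliers, uniform on
  [0.5, 1.5], over the 7 varied inputs (5 plasma zymogens and 2
  thrombin-binding-site densities), and
* a one-at-a-time (OAT) grid for local sensitivity scans, where a single
  input sweeps a set of levels with all others held at baseline.

All randomness flows through :class:`SampleDesign.seed`; identical
designs yield identical matrices.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import VARIABLES, ParameterError

__all__ = ["SampleDesign", "sample_variants", "oat_grid", "write_samples", "read_samples"]

#: default OAT levels: 11 equally spaced points spanning the +-50% range
DEFAULT_OAT_LEVELS = tuple(np.round(np.linspace(0.5, 1.5, 11), 10))


@dataclass(frozen=True)
class SampleDesign:
    """Monte Carlo sampling design for the 7 varied inputs."""

    n: int = 10000
    low: float = 0.5
    high: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError(f"sample count must be >= 1, got {self.n}")
        if not 0 < self.low < self.high:
            raise ParameterError(
                f"need 0 < low < high, got low={self.low}, high={self.high}"
            )


def sample_variants(design: SampleDesign) -> pd.DataFrame:
    """Draw n variant vectors, i.i.d. uniform per input.

    Returns a DataFrame with one row per variant and the canonical column
    order; deterministic for a given design.
    """
    rng = np.random.default_rng(design.seed)
    m = rng.uniform(design.low, design.high, size=(design.n, len(VARIABLES)))
    return pd.DataFrame(m, columns=list(VARIABLES))


def oat_grid(
    levels=DEFAULT_OAT_LEVELS, variables: tuple[str, ...] = VARIABLES
) -> pd.DataFrame:
    """One-at-a-time scan grid: each variable at each level, others at 1.

    The returned frame is indexed by (variable, level) with the all-ones
    baseline included once under the label ("baseline", 1.0).
    """
    unknown = set(variables) - set(VARIABLES)
    if unknown:
        raise ParameterError(f"unknown variables {sorted(unknown)}")
    levels = [float(l) for l in levels]
    for l in levels:
        if not 0.5 <= l <= 1.5:
            raise ParameterError(f"OAT level {l} outside [0.5, 1.5]")

    index = [("baseline", 1.0)]
    rows = [np.ones(len(VARIABLES))]
    for var in variables:
        j = VARIABLES.index(var)
        for level in levels:
            row = np.ones(len(VARIABLES))
            row[j] = level
            index.append((var, level))
            rows.append(row)
    return pd.DataFrame(
        np.array(rows),
        columns=list(VARIABLES),
        index=pd.MultiIndex.from_tuples(index, names=["variable", "level"]),
    )


def write_samples(samples: pd.DataFrame, design: SampleDesign, path: str | Path) -> None:
    """Write the sample matrix as CSV with the design echoed to a JSON sidecar."""
    path = Path(path)
    samples.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".design.json")
    meta = asdict(design)
    meta["rng"] = "numpy.random.default_rng (PCG64)"
    meta["columns"] = list(VARIABLES)
    sidecar.write_text(json.dumps(meta, indent=2))


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, float_precision="round_trip")
    if list(samples.columns) != list(VARIABLES):
        raise ParameterError(
            f"sample file {path} does not have the canonical column order"
        )
    return samples
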