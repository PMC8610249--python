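"""One-at-a-time local sensitivity: max-over-time response per output.

For each variant vector of an OAT grid the model is simulated over the
study horizon and the maximum over the dense output grid of every output
species/flux is recorded, together with its fold change relative to the
all-ones baseline.  This mirrors how local sensitivity is usually
summarized for clotting simulations: the peak concentration reached,
rather than the full dynamics, as a function of each input level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .parameters import VARIABLES, ModelConfig, ParameterError, ParameterSet, build_parameters
from .simulate import SimulationError, simulate

__all__ = ["OUTPUT_COLUMNS", "SensitivityTable", "run_oat", "rank_influence"]

#: outputs tracked by the scan: short name -> trajectory column
OUTPUT_COLUMNS = {
    "IXa": "IXa_nM",
    "Xa": "Xa_nM",
    "XIa": "XIa_nM",
    "IIa_free": "IIa_free_nM",
    "IIa_weakE": "IIa_weakE_nM",
    "IIa_gamma": "IIa_gamma_nM",
    "total_thrombin": "total_thrombin_nM",
    "fibrin": "fibrin_uM",
    "f12_flux": "f12_flux_per_um2_s",
    "tat_flux": "tat_flux_per_um2_s",
}


@dataclass
class SensitivityTable:
    """Long-format OAT results: (variable, level, output) -> value, fold change."""

    table: pd.DataFrame  # columns: variable, level, output, value, fold_change, failed
    baseline: pd.Series  # max-over-time per output for the all-ones vector

    def fold(self, variable: str, level: float, output: str) -> float:
        t = self.table
        sel = t[
            (t["variable"] == variable)
            & (t["level"] == level)
            & (t["output"] == output)
        ]
        if sel.empty:
            raise KeyError((variable, level, output))
        return float(sel["fold_change"].iloc[0])

    def pivot(self, output: str) -> pd.DataFrame:
        """Levels x variables matrix of fold changes for one output."""
        t = self.table[self.table["output"] == output]
        return t.pivot(index="level", columns="variable", values="fold_change")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def run_oat(
    grid: pd.DataFrame, params: ParameterSet, config: ModelConfig
) -> SensitivityTable:
    """Simulate every vector of an OAT grid and tabulate peak fold changes.

    The grid must include the ("baseline", 1.0) row (see
    :func:`clotfilm.sampling.oat_grid`).  Failed integrations are marked
    and skipped; the scan continues.
    """
    if ("baseline", 1.0) not in grid.index:
        raise ParameterError("OAT grid must include the baseline row")

    maxima: dict[tuple, pd.Series | None] = {}
    for key, row in grid.iterrows():
        try:
            traj = simulate(build_parameters(params, config, row.to_numpy()), config)
            maxima[key] = traj.max()
        except SimulationError:
            maxima[key] = None

    base = maxima[("baseline", 1.0)]
    if base is None:
        raise SimulationError("baseline simulation failed; cannot normalize")

    records = []
    for (variable, level), mx in maxima.items():
        for output, column in OUTPUT_COLUMNS.items():
            failed = mx is None
            value = float(mx[column]) if not failed else float("nan")
            base_v = float(base[column])
            fold = value / base_v if (not failed and base_v > 0) else float("nan")
            records.append(
                {
                    "variable": variable,
                    "level": float(level),
                    "output": output,
                    "value": value,
                    "fold_change": fold,
                    "failed": failed,
                }
            )
    table = pd.DataFrame.from_records(records)
    baseline = pd.Series(
        {out: float(base[col]) for out, col in OUTPUT_COLUMNS.items()}, name="baseline"
    )
    return SensitivityTable(table=table, baseline=baseline)


def rank_influence(table: SensitivityTable, output: str) -> list[str]:
    """Rank the 7 inputs by impact on one output at the extreme levels.

    Influence is the largest |fold change - 1| over the two extreme
    levels (0.5 and 1.5); ties break by canonical variable order.
    """
    t = table.table
    scores = {}
    for var in VARIABLES:
        sel = t[
            (t["variable"] == var)
            & (t["level"].isin([0.5, 1.5]))
            & (t["output"] == output)
        ]
        if len(sel) < 2:
            raise ParameterError(
                f"need both extreme levels (0.5, 1.5) for {var!r}; found {len(sel)}"
            )
        scores[var] = float((sel["fold_change"] - 1.0).abs().max())
    return sorted(VARIABLES, key=lambda v: (-scores[v], VARIABLES.index(v)))
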