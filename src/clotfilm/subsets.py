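"""Conditioning the ensemble on extreme fibrin producers and FXIa knockout.

From a Monte Carlo ensemble, the variants producing the most and least
end-time fibrin (top/bottom 2% by rank) and a middle band (50%,
rank-centered on the median) are selected.  Two analyses follow:

* the conditional distributions of the 7 inputs within each subset —
  which input combinations make a strong or weak fibrin producer, and
* the potency of an ideal FXIa inhibitor per subset: each member is
  re-simulated with the FXI feedback rates zeroed and the percent
  reduction in end-time fibrin is averaged over the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import EnsembleResult
from .parameters import (
    VARIABLES,
    ModelConfig,
    ParameterError,
    ParameterSet,
    build_parameters,
)
from .simulate import simulate

__all__ = [
    "SubsetReport",
    "select_percentiles",
    "conditioned_distributions",
    "inhibitor_efficacy",
]

SUBSET_NAMES = ("top_2pct", "middle_50pct", "bottom_2pct")


@dataclass
class SubsetReport:
    """Membership (and, once computed, statistics) of the fibrin subsets."""

    n: int
    tail_fraction: float
    middle_fraction: float
    members: Mapping[str, np.ndarray]  # record labels per subset
    records: pd.DataFrame  # the ensemble per-variant records
    fibrin_column: str = "end_fibrin_uM"
    input_stats: pd.DataFrame | None = None
    input_histograms: dict | None = None
    reductions: pd.DataFrame | None = None
    member_reductions: pd.DataFrame | None = None
    excluded: list = field(default_factory=list)

    def fibrin(self, subset: str) -> pd.Series:
        return self.records.loc[self.members[subset], self.fibrin_column]


def select_percentiles(
    ensemble: EnsembleResult,
    tail_fraction: float = 0.02,
    middle_fraction: float = 0.50,
    fibrin_column: str = "end_fibrin_uM",
) -> SubsetReport:
    """Rank variants by end-time fibrin and mark the study subsets.

    Tails are the ``tail_fraction`` highest/lowest producers; the middle
    band is ``middle_fraction`` of variants rank-centered on the median.
    Ties break by variant index (stable sort), so membership is
    deterministic.
    """
    records = ensemble.records
    n = len(records)
    if n < 100:
        raise ParameterError(f"need >= 100 successful variants, got {n}")
    k = int(round(tail_fraction * n))
    m = int(round(middle_fraction * n))
    if k < 1:
        raise ParameterError(
            f"tail fraction {tail_fraction} selects no variants at n={n}"
        )
    order = records[fibrin_column].to_numpy().argsort(kind="stable")
    labels = records.index.to_numpy()
    start = (n - m) // 2
    members = {
        "top_2pct": labels[order[n - k :]],
        "middle_50pct": labels[order[start : start + m]],
        "bottom_2pct": labels[order[:k]],
    }
    return SubsetReport(
        n=n,
        tail_fraction=tail_fraction,
        middle_fraction=middle_fraction,
        members=members,
        records=records,
        fibrin_column=fibrin_column,
    )


def conditioned_distributions(report: SubsetReport, bins: int = 20) -> pd.DataFrame:
    """Distribution of the 7 inputs within each subset.

    For every input and subset: the conditional mean, sample skewness and
    a direction-of-skew flag relative to the unconditioned uniform
    (mean 1.0, skew 0).  Histograms (common [0.5, 1.5] binning) are
    attached to the report.  Returns the stats table.
    """
    rows = []
    histograms: dict[tuple[str, str], pd.DataFrame] = {}
    edges = np.linspace(0.5, 1.5, bins + 1)
    for subset, labels in report.members.items():
        if len(labels) == 0:
            raise ParameterError(f"subset {subset!r} is empty")
        sub = report.records.loc[labels]
        for var in VARIABLES:
            x = sub[var].to_numpy()
            mean = float(np.mean(x))
            skew = float(stats.skew(x)) if len(x) > 2 else float("nan")
            rows.append(
                {
                    "subset": subset,
                    "variable": var,
                    "mean": mean,
                    "skew": skew,
                    "shifted_up": mean > 1.0,
                }
            )
            counts, _ = np.histogram(x, bins=edges)
            histograms[(subset, var)] = pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            )
    table = pd.DataFrame(rows)
    report.input_stats = table
    report.input_histograms = histograms
    return table


def inhibitor_efficacy(
    report: SubsetReport,
    params: ParameterSet,
    config: ModelConfig,
    progress: bool = False,
) -> pd.DataFrame:
    """Ideal-FXIa-inhibitor potency per subset.

    Every subset member is re-simulated with the FXI feedback switched
    off (both feedback rates zero) and the percent reduction in end-time
    fibrin, 100*(base - knockout)/base, is recorded.  The subset potency
    is the mean over members (median also reported).  Members with zero
    baseline fibrin are excluded and logged.
    """
    ko_config = config.replace(fxi_knockout=True)
    end_only = np.array([0.0, config.t_end])

    labels_all: list = []
    for subset in SUBSET_NAMES:
        labels_all.extend(report.members[subset])
    unique_labels = pd.unique(pd.Index(labels_all))
    iterator = unique_labels
    if progress:
        from tqdm import tqdm

        iterator = tqdm(unique_labels, desc="knockout", unit="sim")

    ko_fibrin: dict = {}
    for label in iterator:
        variant = report.records.loc[label, list(VARIABLES)].to_numpy(dtype=float)
        traj = simulate(
            build_parameters(params, ko_config, variant), ko_config, t_eval=end_only
        )
        ko_fibrin[label] = float(traj.end()["fibrin_uM"])

    member_rows = []
    subset_rows = []
    for subset in SUBSET_NAMES:
        reductions = []
        for label in report.members[subset]:
            base = float(report.records.loc[label, report.fibrin_column])
            if base <= 0:
                report.excluded.append({"subset": subset, "variant": label})
                continue
            red = 100.0 * (base - ko_fibrin[label]) / base
            reductions.append(red)
            member_rows.append(
                {
                    "subset": subset,
                    "variant": label,
                    "fibrin_base_uM": base,
                    "fibrin_knockout_uM": ko_fibrin[label],
                    "percent_reduction": red,
                }
            )
        reductions = np.asarray(reductions)
        subset_rows.append(
            {
                "subset": subset,
                "n_members": len(reductions),
                "mean_percent_reduction": float(np.mean(reductions)),
                "median_percent_reduction": float(np.median(reductions)),
            }
        )
    report.member_reductions = pd.DataFrame(member_rows)
    report.reductions = pd.DataFrame(subset_rows).set_index("subset")
    return report.reductions
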