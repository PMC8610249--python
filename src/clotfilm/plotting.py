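"""Optional figures: OAT fold-change curves and ensemble envelopes.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["plot_oat", "plot_envelope"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_oat(table, output: str, path: str | Path):
    """Fold change of one output vs input level, one curve per input."""
    plt = _mpl()
    pivot = table.pivot(output)
    fig, ax = plt.subplots(figsize=(5, 4))
    for var in pivot.columns:
        if var == "baseline":
            continue
        ax.plot(pivot.index * 100, pivot[var], marker="o", ms=3, label=var)
    ax.axhline(1.0, color="0.6", lw=0.8)
    ax.set_xlabel("input level (% of baseline)")
    ax.set_ylabel(f"peak {output} (fold of baseline)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_envelope(envelope, column: str, path: str | Path):
    """Mean +- SD band and min/max range of one output over time."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    t = envelope["time_s"]
    ax.fill_between(t, envelope["min"], envelope["max"], alpha=0.2, label="range")
    ax.fill_between(
        t,
        envelope["mean"] - envelope["sd"],
        envelope["mean"] + envelope["sd"],
        alpha=0.4,
        label="mean ± SD",
    )
    ax.plot(t, envelope["mean"], lw=1.5, label="mean")
    ax.set_xlabel("time (s)")
    ax.set_ylabel(column)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
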