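"""Optional figure helpers (matplotlib is an extra, not a core dep).

Each function takes the corresponding stage's output table and writes a
single PNG; all styling is intentionally minimal.
"""

from __future__ import annotations

from pathlib import Path


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_selection(table, path: str | Path) -> Path:
    """BIC per candidate, marker-coded by the first-order effect count."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    markers = {0: "o", 1: "s", 2: "^", 3: "x"}
    for nfo, grp in table.groupby("n_first_order"):
        ax.scatter(grp["model"], grp["bic"], marker=markers.get(nfo, "d"),
                   label=f"{nfo} first-order")
    ax.set_ylabel("BIC")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_sobol(result, path: str | Path) -> Path:
    """Grouped bars of first- and total-order indices per output."""
    import numpy as np

    plt = _pyplot()
    n_out = len(result.outputs)
    fig, axes = plt.subplots(1, n_out, figsize=(3.2 * n_out, 3.2),
                             squeeze=False)
    x = np.arange(len(result.inputs))
    for oi, ax in enumerate(axes[0]):
        ax.bar(x - 0.17, result.S[oi], width=0.34, label="S")
        ax.bar(x + 0.17, result.ST[oi], width=0.34, label="ST")
        ax.set_xticks(x, result.inputs, rotation=30, fontsize=8)
        ax.set_title(result.outputs[oi], fontsize=9)
        ax.set_ylim(bottom=0)
    axes[0][0].set_ylabel("Sobol index")
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_protocol_errors(aggregate, path: str | Path) -> Path:
    """Mean recovery error vs sampling period (log-x)."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(aggregate["period_h"], aggregate["mean_error"],
                yerr=aggregate["sd_error"], marker="o")
    ax.set_xscale("log")
    ax.set_xlabel("sampling period (h)")
    ax.set_ylabel("mean parameter error")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_refreshment(table, path: str | Path) -> Path:
    """Terminal population and oscillation amplitude vs refresh period."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["period_days"], table["terminal_n"], marker="o",
            label="terminal population")
    ax.plot(table["period_days"], table["amplitude"], marker="s",
            label="oscillation amplitude")
    ax.set_xlabel("refresh period (days)")
    ax.set_ylabel("cells/well")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
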