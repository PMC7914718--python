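"""Figure helpers for run outputs (requires the optional matplotlib).

Each function takes the tables the engine writes and saves a PNG/SVG:
population curves over time, main-group aspect-ratio bars per fiber
thickness, and arrival/formation timing bars per scenario.
"""

from __future__ import annotations

from pathlib import Path


def _plt():
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("plotting requires matplotlib "
                          "(pip install cardiomech[plot])") from exc
    return plt


def plot_population_curves(metrics_df, path, title="population") -> Path:
    """Counts per phenotype and main-group size against time."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    t = metrics_df["time"]
    ax.plot(t, metrics_df["n_cells"], label="all cells", lw=2)
    ax.plot(t, metrics_df["n_msc"], label="stem cells")
    ax.plot(t, metrics_df["n_cm_early"], label="early CM")
    ax.plot(t, metrics_df["n_cm_late"], label="late CM")
    ax.plot(t, metrics_df["main_group_size"], "--", label="main group")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("cells")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ar_bars(thicknesses, ar_means, path, ar_sds=None,
                 title="main-group aspect ratio") -> Path:
    """Aspect-ratio bars per fiber wall thickness."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    x = range(len(thicknesses))
    ax.bar(x, ar_means, yerr=ar_sds, capsize=3, color="#5b8fc9")
    ax.set_xticks(list(x))
    ax.set_xticklabels([f"{t:g}" for t in thicknesses])
    ax.set_xlabel("fiber wall thickness [um]")
    ax.set_ylabel("AR")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_timing_bars(labels, times, path, ylabel="time [h]",
                     title="timing") -> Path:
    """Timing bars (e.g. time to reach the fiber) per scenario."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    x = range(len(labels))
    ax.bar(x, times, color="#c97a5b")
    ax.set_xticks(list(x))
    ax.set_xticklabels(labels, rotation=20, ha="right", fontsize=8)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
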