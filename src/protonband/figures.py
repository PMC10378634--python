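"""Static summary figures (band envelopes and per-fraction deviations)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["band_figure", "deviation_figure", "save_figures"]

_TIER_COLORS = {"primary": "tab:red", "secondary": "tab:blue", "oar": "tab:gray"}


def band_figure(bands: pd.DataFrame) -> plt.Figure:
    """Per structure/metric, the nominal value with min-max whiskers for each
    setup setting, one panel per patient."""
    patients = sorted(bands["patient"].unique())
    fig, axes = plt.subplots(
        len(patients), 1, figsize=(9, 2.6 * len(patients)), sharex=False, squeeze=False
    )
    setups = sorted(bands["setup_mm"].unique())
    offsets = np.linspace(-0.18, 0.18, len(setups)) if len(setups) > 1 else [0.0]
    for ax, pid in zip(axes.ravel(), patients):
        sub = bands[bands["patient"] == pid]
        labels = [f"{r.structure}\n{r.metric}" for r in
                  sub[sub["setup_mm"] == setups[0]].itertuples()]
        for off, setup in zip(offsets, setups):
            ss = sub[sub["setup_mm"] == setup].reset_index()
            x = np.arange(len(ss)) + off
            yerr = np.vstack(
                [ss["nominal"] - ss["band_min"], ss["band_max"] - ss["nominal"]]
            )
            ax.errorbar(x, ss["nominal"], yerr=yerr, fmt="o", ms=3, capsize=3,
                        label=f"{setup:g} mm")
        ax.set_xticks(np.arange(len(labels)))
        ax.set_xticklabels(labels, fontsize=7)
        ax.set_ylabel("metric value")
        ax.set_title(pid, fontsize=9)
        ax.legend(fontsize=7, title="setup")
    fig.tight_layout()
    return fig


def deviation_figure(records: pd.DataFrame) -> plt.Figure:
    """Out-of-band deviations per patient and setup, colored by target tier."""
    out = records[records["status"] != "inside"]
    setups = sorted(records["setup_mm"].unique())
    fig, axes = plt.subplots(1, len(setups), figsize=(5.5 * len(setups), 4), squeeze=False)
    patients = sorted(records["patient"].unique())
    for ax, setup in zip(axes.ravel(), setups):
        sub = out[(out["setup_mm"] == setup) & (out["metric"].isin(["D95", "V100"]))]
        for i, pid in enumerate(patients):
            for tier, color in _TIER_COLORS.items():
                pts = sub[(sub["patient"] == pid) & (sub["tier"] == tier)]
                if pts.empty:
                    continue
                jitter = np.linspace(-0.15, 0.15, len(pts))
                ax.plot(i + jitter, pts["deviation"], ".", color=color, alpha=0.6,
                        label=tier if i == 0 else None)
        ax.set_xticks(range(len(patients)))
        ax.set_xticklabels(patients, rotation=45, fontsize=7)
        ax.set_ylabel("fractional deviation (% / pp)")
        ax.set_title(f"{setup:g} mm setup uncertainty", fontsize=9)
        handles, labels = ax.get_legend_handles_labels()
        if handles:
            ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def save_figures(bands: pd.DataFrame, records: pd.DataFrame, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fig in (
        ("bands.png", band_figure(bands)),
        ("deviations.png", deviation_figure(records)),
    ):
        path = outdir / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
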