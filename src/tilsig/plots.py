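"""Minimal plot exports: Kaplan-Meier curves and volcano plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .survival import KMCurve  # noqa: E402

__all__ = ["km_plot", "volcano_plot"]


def km_plot(curves: dict[str, KMCurve], path: str | Path) -> None:
    """Step plot of one survival curve per labelled group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=f"{label} (n={curve.n_subjects})")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("disease-specific survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def volcano_plot(deg: pd.DataFrame, path: str | Path,
                 fc_threshold: float = 2.0, p_threshold: float = 0.05) -> None:
    """log2FC vs -log10(p) scatter coloured by volcano class."""
    fig, ax = plt.subplots(figsize=(5, 4))
    logp = -np.log10(np.clip(deg["p_value"], 1e-300, None))
    colors = deg["class"].map({"up": "tab:red", "down": "tab:green",
                               "ns": "lightgray"})
    ax.scatter(deg["log2fc"], logp, s=4, c=colors, linewidths=0)
    ax.axvline(fc_threshold, ls="--", lw=0.8, c="k")
    ax.axvline(-fc_threshold, ls="--", lw=0.8, c="k")
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
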