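"""Minimal matplotlib views of learning curves and sweeps (off by default)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

_MEASURES = [("E_mean", "E_sd", "child error E"),
             ("chi2_mean", "chi2_sd", r"$\chi^2$"),
             ("pearson_mean", "pearson_sd", "Pearson P")]


def plot_learning_curve(curve: pd.DataFrame,
                        path: Optional[Union[str, Path]] = None):
    """Three-panel learning curve (log time axis); optionally saved as PNG."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharex=True)
    for ax, (mean, sd, label) in zip(axes, _MEASURES):
        ax.plot(curve["t"], curve[mean], lw=1.5)
        ax.fill_between(curve["t"], curve[mean] - curve[sd],
                        curve[mean] + curve[sd], alpha=0.25, lw=0)
        ax.set_xscale("log")
        ax.set_xlabel("time $t$ (iterations = corpus size)")
        ax.set_ylabel(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_sweep_cross_section(cross: pd.DataFrame, param_name: str = "m",
                             path: Optional[Union[str, Path]] = None):
    """Final measures against the memory parameter (the U-shape view)."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), sharex=True)
    for ax, (mean, sd, label) in zip(axes, _MEASURES):
        ax.errorbar(cross["param_value"], cross[mean], yerr=cross[sd],
                    fmt="o-", ms=3, lw=1)
        ax.set_xscale("log")
        ax.set_xlabel(param_name)
        ax.set_ylabel(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
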