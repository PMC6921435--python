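"""Figure helpers: G/NG spectrum overlays and cohort pattern matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .spectral import PSDEstimate

__all__ = ["plot_psd_overlay", "plot_pattern_matrix"]

_DIRECTION_COLOR = {"I": "#d62728", "D": "#1f77b4", "E": "#bdbdbd"}


def plot_psd_overlay(g: PSDEstimate, ng: PSDEstimate, title: str = "",
                     path: str | Path | None = None):
    """Overlay one participant's glucose and control spectra for a segment."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(g.frequency_hz, g.power, label="G", color="#1f77b4")
    ax.plot(ng.frequency_hz, ng.power, label="NG", color="#ff7f0e")
    ax.set_xlabel("frequency (beat-domain Hz)")
    ax.set_ylabel("power")
    ax.set_title(title or f"{g.segment_id} PSD")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_pattern_matrix(direction_matrix: pd.DataFrame, segment: str,
                        path: str | Path | None = None):
    """Participants x parameters direction grid for one segment (I/D/E colors)."""
    sub = direction_matrix[direction_matrix["segment"] == segment]
    pivot = sub.pivot(index="participant", columns="parameter", values="direction")
    codes = pivot.replace({"I": 0, "D": 1, "E": 2}).to_numpy(dtype=float)
    cmap = matplotlib.colors.ListedColormap(
        [_DIRECTION_COLOR["I"], _DIRECTION_COLOR["D"], _DIRECTION_COLOR["E"]])
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * pivot.shape[1],
                                    1.0 + 0.3 * pivot.shape[0]))
    ax.imshow(codes, cmap=cmap, vmin=0, vmax=2, aspect="auto")
    ax.set_xticks(np.arange(pivot.shape[1]), pivot.columns)
    ax.set_yticks(np.arange(pivot.shape[0]), pivot.index)
    ax.set_title(f"{segment}: direction per participant (red=I, blue=D, grey=E)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
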