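"""Visualization idioms for beat-level explanation.

Three overlays: (1) the interval heat strip — the signal over per-RR-
interval background shading, red for target-class evidence and blue
against, with yellow R-peak markers; (2) a gallery of the top-ranked
beats with surrounding context; (3) the Grad-CAM overlay with green
highlight regions.  All figures render with a fixed style and DPI so
repeated calls produce identical files.
"""

from __future__ import annotations

from typing import List, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.cm import ScalarMappable
from matplotlib.colors import Normalize

from .aggregate import AggregationReport, IntervalScore, interval_color_values
from .beats import RPeakSet
from .gradcam import CamMap, highlight_regions
from .records import EcgRecord, Rhythm

__all__ = ["plot_interval_heatmap", "plot_beat_gallery", "plot_gradcam_overlay"]

_STYLE = {
    "figure.dpi": 100,
    "savefig.dpi": 100,
    "font.size": 9,
    "axes.grid": False,
    "svg.hashsalt": "ecgxai",
}


def _save(fig, path: str) -> str:
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
    return str(path)


def plot_interval_heatmap(
    record: EcgRecord,
    report: AggregationReport,
    rpeaks: RPeakSet,
    path: str,
) -> str:
    """Signal trace over red/blue per-interval shading, R-peaks in yellow."""
    if rpeaks.indices.size and rpeaks.indices[-1] >= record.n_samples:
        raise ValueError("R-peaks not aligned to record")
    with plt.rc_context(_STYLE):
        fig, ax = plt.subplots(figsize=(12, 3))
        t = np.arange(record.n_samples) / record.fs
        cmap = plt.get_cmap("RdBu_r")
        norm = Normalize(vmin=-1, vmax=1)
        for score, intensity in zip(report.scores, interval_color_values(report)):
            ax.axvspan(
                score.interval.start / record.fs,
                score.interval.end / record.fs,
                color=cmap(norm(intensity)),
                alpha=0.5,
                linewidth=0,
            )
        ax.plot(t, record.samples, color="black", linewidth=0.7, label="ECG")
        ax.plot(
            rpeaks.indices / record.fs,
            record.samples[rpeaks.indices],
            "v",
            color="gold",
            markersize=6,
            label="R peak",
        )
        sm = ScalarMappable(norm=norm, cmap=cmap)
        cbar = fig.colorbar(sm, ax=ax, pad=0.01)
        cbar.set_label("interval score (red = target-class evidence)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mV")
        ax.legend(loc="upper right")
        ax.set_title(f"{record.record_id}: RR-interval importance")
        fig.tight_layout()
        return _save(fig, path)


def plot_beat_gallery(
    record: EcgRecord,
    top: Sequence[IntervalScore],
    context: float,
    path: str,
) -> str:
    """One panel per top-ranked interval, with ±context seconds around it."""
    if not top:
        raise ValueError("need at least one interval to plot")
    with plt.rc_context(_STYLE):
        k = len(top)
        fig, axes = plt.subplots(1, k, figsize=(3.2 * k, 2.6), squeeze=False)
        for ax, score in zip(axes[0], top):
            lo = max(0, score.interval.start - int(round(context * record.fs)))
            hi = min(record.n_samples, score.interval.end + int(round(context * record.fs)))
            t = np.arange(lo, hi) / record.fs
            ax.plot(t, record.samples[lo:hi], color="black", linewidth=0.8)
            ax.axvspan(
                score.interval.start / record.fs,
                score.interval.end / record.fs,
                color="red" if score.raw_score >= 0 else "blue",
                alpha=0.15,
                linewidth=0,
            )
            ax.set_title(f"rank {score.rank}, score {score.raw_score:+.3g}")
            ax.set_xlabel("time (s)")
        axes[0][0].set_ylabel("mV")
        fig.tight_layout()
        return _save(fig, path)


def plot_gradcam_overlay(record: EcgRecord, cam: CamMap, path: str) -> str:
    """Waveform (blue sinus / red AFib) with green Grad-CAM highlights."""
    with plt.rc_context(_STYLE):
        fig, ax = plt.subplots(figsize=(12, 3))
        t = np.arange(record.n_samples) / record.fs
        color = "red" if record.label is Rhythm.AFIB else "blue"
        ax.plot(t, record.samples, color=color, linewidth=0.7)
        for start, end in highlight_regions(cam, cam.threshold_quantile):
            ax.axvspan(start / record.fs, end / record.fs, color="green", alpha=0.25, linewidth=0)
        ax2 = ax.twinx()
        ax2.plot(t, cam.activation, color="darkgreen", linewidth=0.5, alpha=0.6)
        ax2.set_ylabel("Grad-CAM activation")
        ax2.set_ylim(0, 1.05)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("mV")
        ax.set_title(f"{record.record_id}: Grad-CAM ({cam.target_class.value})")
        fig.tight_layout()
        return _save(fig, path)
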