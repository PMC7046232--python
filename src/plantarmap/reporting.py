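"""QC figures and cohort-level pattern summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pressure_io import PressureImage
from .spm_outliers import PATTERN_NAMES, AbnormalityMap, PatternReport, TMap

__all__ = ["six_panel_figure", "overlay_figure", "pattern_summary", "save_image_png"]


def save_image_png(image: PressureImage, path: str | Path, title: str | None = None) -> None:
    """Quick-look PNG export of a pressure image."""
    fig, ax = plt.subplots(figsize=(3, 5))
    ax.imshow(image.data.T, origin="lower", cmap="inferno")
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def overlay_figure(fixed: PressureImage, moving: PressureImage, path: str | Path) -> None:
    """Alignment QC overlay: fixed image in red, moving image in blue."""
    rgb = np.zeros((*fixed.data.shape, 3))
    fmax = fixed.data.max() or 1.0
    mmax = moving.data.max() or 1.0
    rgb[..., 0] = np.clip(fixed.data / fmax, 0, 1)
    rgb[..., 2] = np.clip(moving.data / mmax, 0, 1)
    fig, ax = plt.subplots(figsize=(3, 5))
    ax.imshow(np.transpose(rgb, (1, 0, 2)), origin="lower")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def six_panel_figure(
    measured: PressureImage,
    aligned: PressureImage,
    predicted: PressureImage,
    tmap: TMap,
    abmap: AbnormalityMap,
    path: str | Path,
) -> None:
    """Per-foot QC panel: measured, aligned, predicted, overlay, raw t, thresholded t."""
    fig, axes = plt.subplots(1, 6, figsize=(16, 5))
    pressure_panels = [
        (measured.data, "measured"),
        (aligned.data, "aligned"),
        (predicted.data, "predicted"),
    ]
    vmax = max(p.max() for p, _ in pressure_panels) or 1.0
    for ax, (data, title) in zip(axes[:3], pressure_panels):
        ax.imshow(data.T, origin="lower", cmap="inferno", vmin=0, vmax=vmax)
        ax.set_title(title, fontsize=9)
        ax.set_axis_off()

    rgb = np.zeros((*predicted.data.shape, 3))
    pmax = predicted.data.max() or 1.0
    amax = aligned.data.max() or 1.0
    rgb[..., 0] = np.clip(predicted.data / pmax, 0, 1)
    rgb[..., 2] = np.clip(aligned.data / amax, 0, 1)
    axes[3].imshow(np.transpose(rgb, (1, 0, 2)), origin="lower")
    axes[3].set_title("overlay (pred=red)", fontsize=9)
    axes[3].set_axis_off()

    tmax = max(np.abs(tmap.t).max(), abmap.critical_t) or 1.0
    for ax, data, title in (
        (axes[4], tmap.t, "SPM{t}"),
        (axes[5], abmap.thresholded_t, f"|t| >= {abmap.critical_t:.2f}"),
    ):
        im = ax.imshow(data.T, origin="lower", cmap="coolwarm", vmin=-tmax, vmax=tmax)
        ax.set_title(title, fontsize=9)
        ax.set_axis_off()
    fig.colorbar(im, ax=axes[5], fraction=0.05)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def pattern_summary(reports: dict[str, PatternReport]) -> pd.DataFrame:
    """Per-foot boolean pattern table plus a prevalence summary row attribute.

    One row per foot-case with the five pattern flags and ``no_abnormality``;
    the returned frame's ``attrs['prevalence']`` holds the cohort fractions.
    """
    rows = []
    for foot_id, report in reports.items():
        row = {"foot_id": foot_id}
        row.update(report.to_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = list(PATTERN_NAMES) + ["no_abnormality"]
    df.attrs["prevalence"] = {c: float(df[c].mean()) for c in cols} if len(df) else {}
    return df
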