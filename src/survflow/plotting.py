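"""Static plot export for KM curves and nomograms (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .km import KaplanMeierCurve
from .nomogram import NomogramSpec

__all__ = ["plot_km", "plot_nomogram"]


def _step_xy(curve: KaplanMeierCurve) -> tuple[np.ndarray, np.ndarray]:
    x = np.concatenate([[0.0], curve.event_times])
    y = np.concatenate([[1.0], curve.survival])
    return x, y


def plot_km(
    curves: dict[object, KaplanMeierCurve],
    path: str,
    ci_band: bool = True,
    title: str | None = None,
) -> None:
    """Step-function survival curves (one per group) with optional CI bands."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        x, y = _step_xy(curve)
        (line,) = ax.step(x, y, where="post", label=str(label))
        if ci_band:
            ax.fill_between(
                curve.event_times,
                curve.ci_lower,
                curve.ci_upper,
                step="post",
                alpha=0.2,
                color=line.get_color(),
            )
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    if len(curves) > 1:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_nomogram(nomogram: NomogramSpec, model, path: str, n_ticks: int = 6) -> None:
    """Aligned point axes per feature, a total-points axis, and one survival
    axis per horizon."""
    from .nomogram import survival_from_total_points

    k = len(nomogram.feature_names)
    n_h = len(nomogram.horizons)
    fig, ax = plt.subplots(figsize=(8, 1.2 * (k + 2 + n_h)))
    rows = k + 2 + n_h
    ax.set_xlim(-15, 105)
    ax.set_ylim(-0.5, rows - 0.5)
    ax.axis("off")

    def axis_row(y, label, ticks, tick_labels):
        ax.plot([0, 100], [y, y], color="black", lw=1)
        ax.text(-14, y, label, va="center", fontsize=9)
        for tx, tl in zip(ticks, tick_labels):
            ax.plot([tx, tx], [y - 0.08, y + 0.08], color="black", lw=1)
            ax.text(tx, y + 0.14, tl, ha="center", fontsize=7)

    y = rows - 1
    axis_row(y, "points", np.linspace(0, 100, n_ticks), [f"{v:g}" for v in np.linspace(0, 100, n_ticks)])
    for j, name in enumerate(nomogram.feature_names):
        y -= 1
        span = nomogram.max_points[j]
        vals = np.linspace(nomogram.observed_min[j], nomogram.observed_max[j], n_ticks)
        pts = (vals - nomogram.reference_values[j]) * nomogram.points_per_unit[j]
        axis_row(y, name, pts if span > 0 else [0], [f"{v:.3g}" for v in vals])
    y -= 1
    total_max = float(nomogram.max_points.sum())
    ticks = np.linspace(0, total_max, n_ticks)
    axis_row(
        y,
        "total points",
        np.linspace(0, 100, n_ticks),
        [f"{v:.3g}" for v in ticks],
    )
    surv = survival_from_total_points(nomogram, model, ticks)
    for hi, h in enumerate(nomogram.horizons):
        y -= 1
        axis_row(
            y,
            f"S(t={h:g})",
            np.linspace(0, 100, n_ticks),
            [f"{s:.2f}" for s in surv[:, hi]],
        )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
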