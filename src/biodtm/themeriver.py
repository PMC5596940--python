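"""ThemeRiver layout and SVG rendering.

Streams are stacked in topic-id order around a straight horizontal
baseline: at each slice anchor the band is symmetric about y = 0 and its
height equals the (scaled) strength sum.  Between anchors every stream
width is interpolated with a monotone piecewise cubic (PCHIP), which
cannot overshoot, so widths never go negative and streams tile the band
exactly everywhere — boundaries are cumulative sums of widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .topic_analysis import TopicStrengthMatrix

__all__ = ["RiverLayout", "LayoutError", "layout", "render_svg", "render_png",
           "DEFAULT_PALETTE"]


class LayoutError(ValueError):
    pass


# 20 distinguishable hex colors (the familiar tab20 cycle)
DEFAULT_PALETTE = (
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
    "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
    "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
    "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
)


@dataclass
class RiverLayout:
    x: np.ndarray  # (P,) interpolated horizontal positions
    lower: np.ndarray  # (K, P) stream lower envelopes
    upper: np.ndarray  # (K, P) stream upper envelopes
    anchor_x: np.ndarray  # (T,) anchor positions
    anchor_idx: np.ndarray  # (T,) indices of anchors within x

    @property
    def K(self) -> int:
        return self.lower.shape[0]

    def widths(self) -> np.ndarray:
        return self.upper - self.lower


def layout(
    strengths: TopicStrengthMatrix | np.ndarray,
    samples_per_gap: int = 20,
    scale: float = 1.0,
    x_positions: np.ndarray | None = None,
) -> RiverLayout:
    """Compute the stacked-stream envelopes.

    ``x_positions`` (length T) overrides the default equal spacing of
    slice anchors, e.g. to place slices proportionally to calendar years.
    """
    s = strengths.s if isinstance(strengths, TopicStrengthMatrix) else np.asarray(strengths, dtype=float)
    if s.ndim != 2:
        raise LayoutError("strengths must be a (K, T) matrix")
    K, T = s.shape
    if T < 2:
        raise LayoutError("at least two slices are required for a river layout")
    if np.any(s < 0):
        raise LayoutError("strengths must be non-negative")
    ax = (
        np.asarray(x_positions, dtype=float)
        if x_positions is not None
        else np.arange(T, dtype=float)
    )
    if ax.shape != (T,) or np.any(np.diff(ax) <= 0):
        raise LayoutError("x_positions must be strictly increasing of length T")
    if samples_per_gap < 1:
        raise LayoutError("samples_per_gap must be >= 1")

    pieces = [
        np.linspace(ax[t], ax[t + 1], samples_per_gap + 1)[:-1] for t in range(T - 1)
    ]
    x = np.concatenate(pieces + [ax[-1:]])
    anchor_idx = np.arange(T) * samples_per_gap

    widths_anchor = s * scale  # (K, T)
    widths = np.empty((K, len(x)))
    for k in range(K):
        widths[k] = PchipInterpolator(ax, widths_anchor[k])(x)
    total = widths.sum(axis=0)
    base = -0.5 * total
    cum = np.concatenate([np.zeros((1, len(x))), np.cumsum(widths, axis=0)], axis=0)
    lower = base[None, :] + cum[:-1]
    upper = base[None, :] + cum[1:]
    return RiverLayout(x=x, lower=lower, upper=upper, anchor_x=ax, anchor_idx=anchor_idx)


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def render_svg(
    river: RiverLayout,
    path: str | Path,
    colors: list[str] | None = None,
    labels: list[str] | None = None,
    tick_labels: list[str] | None = None,
    width: int = 960,
    height: int = 480,
) -> Path:
    """Write a standalone deterministic SVG: one closed <path> per topic,
    axis ticks with slice labels, and a colour legend."""
    K = river.K
    if colors is None:
        colors = [DEFAULT_PALETTE[k % len(DEFAULT_PALETTE)] for k in range(K)]
    if labels is None:
        labels = [f"topic {k + 1}" for k in range(K)]
    if tick_labels is None:
        tick_labels = [str(t + 1) for t in range(len(river.anchor_x))]

    legend_w = 130
    ml, mr, mt, mb = 40, 20 + legend_w, 20, 50
    plot_w = width - ml - mr
    plot_h = height - mt - mb

    x0, x1 = float(river.x[0]), float(river.x[-1])
    ymax = max(float(np.abs(river.lower).max()), float(np.abs(river.upper).max()), 1e-12)

    def sx(v: float) -> float:
        return ml + (v - x0) / (x1 - x0) * plot_w

    def sy(v: float) -> float:
        return mt + plot_h / 2 - v / ymax * (plot_h / 2)

    out = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">'
    )
    out.append(f'<rect width="{width}" height="{height}" fill="white"/>')
    for k in range(K):
        pts = [
            f"{_fmt(sx(float(x)))},{_fmt(sy(float(y)))}"
            for x, y in zip(river.x, river.upper[k])
        ]
        pts_back = [
            f"{_fmt(sx(float(x)))},{_fmt(sy(float(y)))}"
            for x, y in zip(river.x[::-1], river.lower[k][::-1])
        ]
        d = "M " + " L ".join(pts + pts_back) + " Z"
        out.append(
            f'<path d="{d}" fill="{colors[k]}" stroke="none" fill-opacity="0.9"/>'
        )
    # horizontal axis with slice ticks
    axis_y = mt + plot_h + 8
    out.append(
        f'<line x1="{_fmt(ml)}" y1="{_fmt(axis_y)}" x2="{_fmt(ml + plot_w)}" '
        f'y2="{_fmt(axis_y)}" stroke="black" stroke-width="1"/>'
    )
    for t, axv in enumerate(river.anchor_x):
        tx = sx(float(axv))
        out.append(
            f'<line x1="{_fmt(tx)}" y1="{_fmt(axis_y)}" x2="{_fmt(tx)}" '
            f'y2="{_fmt(axis_y + 5)}" stroke="black" stroke-width="1"/>'
        )
        label = tick_labels[t] if t < len(tick_labels) else str(t + 1)
        out.append(
            f'<text x="{_fmt(tx)}" y="{_fmt(axis_y + 18)}" font-size="10" '
            f'text-anchor="middle" font-family="sans-serif">{label}</text>'
        )
    # legend
    lx = width - legend_w - 10
    for k in range(K):
        ly = mt + 14 * k
        out.append(
            f'<rect x="{_fmt(lx)}" y="{_fmt(ly)}" width="10" height="10" '
            f'fill="{colors[k]}"/>'
        )
        out.append(
            f'<text x="{_fmt(lx + 14)}" y="{_fmt(ly + 9)}" font-size="10" '
            f'font-family="sans-serif">{labels[k]}</text>'
        )
    out.append("</svg>")
    path = Path(path)
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


def render_png(river: RiverLayout, path: str | Path,
               colors: list[str] | None = None,
               labels: list[str] | None = None) -> Path:
    """Optional raster rendering via matplotlib (lazy import)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K = river.K
    if colors is None:
        colors = [DEFAULT_PALETTE[k % len(DEFAULT_PALETTE)] for k in range(K)]
    fig, axp = plt.subplots(figsize=(10, 5))
    for k in range(K):
        axp.fill_between(river.x, river.lower[k], river.upper[k],
                         color=colors[k], alpha=0.9,
                         label=labels[k] if labels else None)
    axp.set_yticks([])
    if labels:
        axp.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
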