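"""Image-based promoter patterns and per-promoter summaries.

A promoter pattern is the 2-D figure obtained by drawing, for each sliding
window, a vertical line at x = relative (C+G)% running from the baseline up to
y = KIC%.  A 500 nt promoter profiled at window 30 / step 1 therefore renders
as 470 lines; clusters of lines betray homopolymer tracts and CpG-dense
stretches.  Lines are coloured blue -> red by how many lines share the same
(binned) x position, and the pattern's *center of weight* — the unweighted
mean of the line coordinates — condenses the whole pattern to a single point
used for genome-wide distribution plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kic import WindowProfile
from .sequence_io import PromoterRecord

__all__ = [
    "PromoterPattern",
    "PromoterSummary",
    "build_pattern",
    "summarize_promoter",
    "render_pattern",
    "pattern_table",
]


@dataclass
class PromoterPattern:
    """Renderable pattern: vertical lines, overlap densities, center of weight."""

    promoter_id: str
    x: np.ndarray  # relative (C+G)% per line
    y_top: np.ndarray  # KIC% per line; lines run from y=0 to y_top
    density: np.ndarray  # per-line overlap count (lines sharing the same x bin)
    bin_width: float
    center_of_weight: tuple[float, float]

    @property
    def n_lines(self) -> int:
        return len(self.x)


@dataclass
class PromoterSummary:
    """Per-promoter scalar statistics derived from its window profile."""

    promoter_id: str
    gene: str | None
    phenotype: str
    mean_kic: float
    median_kic: float
    cg_total: float
    mean_cg_window: float
    center_of_weight: tuple[float, float]


def build_pattern(
    profile: WindowProfile, bin_width: float = 0.5, density_weighted: bool = False
) -> PromoterPattern:
    """Build the pattern for one profile.

    One vertical line per window at ``x = cg_value`` spanning the baseline to
    ``y = kic_value``.  Overlap density is counted on x quantized to
    ``bin_width`` percentage points (continuous x values never coincide
    exactly).  The center of weight is the component-wise mean of the line
    coordinates, each window contributing equally; with
    ``density_weighted=True`` each line is instead weighted by its bin's
    overlap count, emphasising dense clusters.
    """
    if profile.n_windows == 0:
        raise ValueError(f"profile {profile.promoter_id!r} has no windows")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(profile.cg_values, dtype=float)
    y = np.asarray(profile.kic_values, dtype=float)
    bins = np.floor(x / bin_width).astype(np.int64)
    _, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    density = counts[inverse]
    if density_weighted:
        center = (
            float(np.average(x, weights=density)),
            float(np.average(y, weights=density)),
        )
    else:
        center = (float(x.mean()), float(y.mean()))
    return PromoterPattern(
        promoter_id=profile.promoter_id,
        x=x,
        y_top=y,
        density=density,
        bin_width=bin_width,
        center_of_weight=center,
    )


def summarize_promoter(profile: WindowProfile, record: PromoterRecord | None = None) -> PromoterSummary:
    """Collapse a profile to per-promoter scalars.

    ``mean_kic`` is the arithmetic mean of the (already rounded) per-window
    KIC values — the per-promoter "Kappa IC" used in cohort statistics.
    ``median_kic`` is the standard median.  The center of weight equals
    ``(mean_cg_window, mean_kic)``.
    """
    if profile.n_windows == 0:
        raise ValueError(f"profile {profile.promoter_id!r} has no windows")
    mean_kic = float(profile.kic_values.mean())
    mean_cg = float(profile.cg_values.mean())
    return PromoterSummary(
        promoter_id=profile.promoter_id,
        gene=record.gene if record is not None else None,
        phenotype=record.phenotype if record is not None else "UNLABELED",
        mean_kic=mean_kic,
        median_kic=float(np.median(profile.kic_values)),
        cg_total=float(profile.cg_total),
        mean_cg_window=mean_cg,
        center_of_weight=(mean_cg, mean_kic),
    )


def pattern_table(pattern: PromoterPattern):
    """Pattern lines as a DataFrame: promoter_id, x, y_top, density_bin."""
    import pandas as pd

    return pd.DataFrame(
        {
            "promoter_id": pattern.promoter_id,
            "x": pattern.x,
            "y_top": pattern.y_top,
            "density_bin": pattern.density,
        }
    )


def render_pattern(
    pattern: PromoterPattern,
    out_path,
    *,
    figsize: tuple[float, float] = (5.0, 5.0),
    dpi: int = 150,
    title: str | None = None,
) -> None:
    """Render a pattern to PNG or SVG (chosen by the output suffix).

    Axes are fixed to [0, 100] on both sides (percent scales); line colour is
    mapped linearly blue -> red over overlap density 1 .. max; the center of
    weight is drawn as a black circle.  Output is deterministic for a fixed
    pattern and style: SVG hash salts and date metadata are pinned.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    with matplotlib.rc_context({"svg.hashsalt": "promarch"}):
        fig, ax = plt.subplots(figsize=figsize, dpi=dpi)
        dmax = int(pattern.density.max())
        cmap = plt.get_cmap("coolwarm")
        norm = matplotlib.colors.Normalize(vmin=1, vmax=max(dmax, 2))
        segments = [((xi, 0.0), (xi, yi)) for xi, yi in zip(pattern.x, pattern.y_top)]
        lc = LineCollection(segments, colors=cmap(norm(pattern.density)), linewidths=0.8)
        ax.add_collection(lc)
        cx, cy = pattern.center_of_weight
        ax.plot([cx], [cy], "o", color="black", markersize=7, zorder=3)
        ax.set_xlim(0, 100)
        ax.set_ylim(0, 100)
        ax.set_xlabel("relative (C+G)%")
        ax.set_ylabel("Kappa IC (%)")
        ax.set_title(title if title is not None else pattern.promoter_id)
        fig.savefig(out_path, metadata=_static_metadata(str(out_path)))
        plt.close(fig)


def _static_metadata(path: str) -> dict:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": "promarch"}
    return {}
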