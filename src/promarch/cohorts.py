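"""Cohort-level analysis of promoter summaries.

Aggregates per-promoter summaries into phenotype-group statistics, compares
two groups with a rank-based test, partitions a panel into core and
intermediary promoters with an explicit geometric rule, and computes
center-of-weight distributions for genome-wide backgrounds.

The intermediary rule formalizes the idea that some promoters sit *between*
the two phenotype clouds on the (total (C+G)%, mean KIC) plane: each core
group contributes an interquartile box; promoters in the overlap of the two
boxes, or stranded in the convex hull spanned between them while falling
outside their own (whisker-expanded) box, are called INTERMEDIARY.  Box
estimation is iterated so that promoters already flagged as intermediary do
not inflate their group's box.  All thresholds live in
:class:`PartitionRule` and serialize to plain dicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import MultiPoint, Point, box as shapely_box

from .kic import WindowParams, window_profile
from .patterns import PromoterSummary, summarize_promoter
from .sequence_io import PromoterRecord

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "PartitionRule",
    "PhenotypePartition",
    "summarize_group",
    "compare_groups",
    "classify_intermediary",
    "background_distribution",
]


@dataclass
class GroupSummary:
    """Summary statistics for one phenotype group, extremes with gene attribution."""

    phenotype: str
    n: int
    mean_kic: float
    median_kic: float
    mean_cg: float
    median_cg: float
    kic_range: tuple[tuple[float, str], tuple[float, str]]  # (min, gene), (max, gene)
    cg_range: tuple[tuple[float, str], tuple[float, str]]
    promoter_classes: tuple[str, ...] = ()  # optional descriptive labels


@dataclass
class ComparisonResult:
    statistic_name: str
    statistic: float
    p_value: float
    axis: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _attr(summary: PromoterSummary) -> str:
    return summary.gene or summary.promoter_id


def summarize_group(summaries: Sequence[PromoterSummary], phenotype: str) -> GroupSummary:
    """Aggregate the summaries carrying the requested phenotype label.

    Means and medians are taken over per-promoter ``mean_kic`` and
    ``cg_total``; the extremes carry the gene symbol (or promoter id) of the
    promoter attaining them.
    """
    members = [s for s in summaries if s.phenotype == phenotype]
    if not members:
        raise ValueError(f"no summaries with phenotype {phenotype!r}")
    kic = np.array([s.mean_kic for s in members])
    cg = np.array([s.cg_total for s in members])
    i_kmin, i_kmax = int(np.argmin(kic)), int(np.argmax(kic))
    i_cmin, i_cmax = int(np.argmin(cg)), int(np.argmax(cg))
    return GroupSummary(
        phenotype=phenotype,
        n=len(members),
        mean_kic=float(kic.mean()),
        median_kic=float(np.median(kic)),
        mean_cg=float(cg.mean()),
        median_cg=float(np.median(cg)),
        kic_range=(
            (float(kic[i_kmin]), _attr(members[i_kmin])),
            (float(kic[i_kmax]), _attr(members[i_kmax])),
        ),
        cg_range=(
            (float(cg[i_cmin]), _attr(members[i_cmin])),
            (float(cg[i_cmax]), _attr(members[i_cmax])),
        ),
    )


_AXES = ("mean_kic", "cg_total")


def _axis_values(summaries: Iterable[PromoterSummary], axis: str) -> np.ndarray:
    return np.array([getattr(s, axis) for s in summaries], dtype=float)


def _rank_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Asymptotic Mann-Whitney without continuity correction so that
    # identical samples give z = 0 and p = 1 exactly.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    u, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):  # zero variance after tie correction: no evidence either way
        p = 1.0
    return u, p


def _holm(pvalues: Sequence[float]) -> list[float]:
    order = np.argsort(pvalues)
    m = len(pvalues)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def compare_groups(
    a: Sequence[PromoterSummary],
    b: Sequence[PromoterSummary],
    axis: str = "mean_kic",
    *,
    test: str = "rank",
) -> ComparisonResult:
    """Two-group architecture comparison on one axis (or jointly on both).

    Default is the two-sided Mann-Whitney rank test, appropriate for the
    small group sizes typical of disease panels (n around 15); ``test="welch"``
    switches to the unequal-variance t-test on means.  ``axis="joint"`` tests
    both ``mean_kic`` and ``cg_total`` and reports the smaller Holm-adjusted
    p-value (with the statistic of the corresponding axis).
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members for a comparison")
    if test not in ("rank", "welch"):
        raise ValueError(f"unknown test {test!r}")

    def one(ax: str) -> tuple[str, float, float]:
        x, y = _axis_values(a, ax), _axis_values(b, ax)
        if test == "rank":
            u, p = _rank_test(x, y)
            return "mannwhitney_u", u, p
        res = stats.ttest_ind(x, y, equal_var=False)
        return "welch_t", float(res.statistic), float(res.pvalue)

    if axis in _AXES:
        name, statistic, p = one(axis)
        return ComparisonResult(name, statistic, p, axis)
    if axis == "joint":
        results = [one(ax) for ax in _AXES]
        adjusted = _holm([p for _, _, p in results])
        best = int(np.argmin(adjusted))
        name, statistic, _ = results[best]
        return ComparisonResult(
            f"{name}[{_AXES[best]}]+holm", statistic, adjusted[best], "joint"
        )
    raise ValueError(f"unknown axis {axis!r}; expected one of {_AXES + ('joint',)}")


@dataclass(frozen=True)
class PartitionRule:
    """Explicit, serializable parameters of the core/intermediary partition.

    The core box is each group's interquartile box per axis.  With
    ``box_estimator="mad"`` (default) the box is the robust estimate
    ``median +/- MAD`` per axis — for symmetric data the MAD equals half the
    IQR, so this estimates the same box but keeps a 50% breakdown point, so
    a minority of genuinely intermediary promoters inside a group cannot
    stretch the very box that is supposed to exclude them;
    ``box_estimator="quantile"`` uses the plain ``core_quantiles`` instead.
    ``whisker`` expands the boxes by that multiple of the (estimated) IQR per
    side before the between-group hull is spanned, which sets the hull's
    vertical generosity.  ``gap_margin`` is the fraction of the horizontal
    gap between the two boxes a promoter must have crossed, starting from its
    own group's side, before it can be called stranded — a scale-free guard
    that tolerates ordinary within-group spread on the CG axis.
    ``refine_iterations`` > 1 re-estimates the boxes after dropping promoters
    no longer labeled with their own core label (off by default: the robust
    box makes refinement unnecessary, and feedback can shrink the boxes on
    clean panels).
    """

    x_axis: str = "cg_total"
    y_axis: str = "mean_kic"
    box_estimator: str = "mad"
    core_quantiles: tuple[float, float] = (0.25, 0.75)
    whisker: float = 2.0
    gap_margin: float = 0.25
    refine_iterations: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhenotypePartition:
    labels: dict[str, str]  # promoter_id -> CORE_<phenotype> | INTERMEDIARY
    rule_params: dict
    boxes: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)


def _quantile_box(pts: np.ndarray, rule: PartitionRule, phenotype: str):
    if rule.box_estimator == "mad":
        med = np.median(pts, axis=0)
        mad = np.median(np.abs(pts - med), axis=0)
        x0, x1 = med[0] - mad[0], med[0] + mad[0]
        y0, y1 = med[1] - mad[1], med[1] + mad[1]
    elif rule.box_estimator == "quantile":
        qlo, qhi = rule.core_quantiles
        x0, x1 = np.quantile(pts[:, 0], [qlo, qhi])
        y0, y1 = np.quantile(pts[:, 1], [qlo, qhi])
    else:
        raise ValueError(f"unknown box_estimator {rule.box_estimator!r}")
    if x1 <= x0 or y1 <= y0:
        warnings.warn(
            f"degenerate core box for group {phenotype!r}; falling back to range box",
            stacklevel=2,
        )
        x0, x1 = pts[:, 0].min(), pts[:, 0].max()
        y0, y1 = pts[:, 1].min(), pts[:, 1].max()
        if x1 <= x0:
            x0, x1 = x0 - 0.5, x1 + 0.5
        if y1 <= y0:
            y0, y1 = y0 - 0.5, y1 + 0.5
    return x0, y0, x1, y1


def _expand(bounds, wx: float, wy: float):
    x0, y0, x1, y1 = bounds
    return x0 - wx, y0 - wy, x1 + wx, y1 + wy


def classify_intermediary(
    summaries: Sequence[PromoterSummary],
    rule: PartitionRule = PartitionRule(),
) -> PhenotypePartition:
    """Partition a two-phenotype panel into core and intermediary promoters.

    Labels: a promoter inside both core boxes is INTERMEDIARY; inside exactly
    one box it takes that box's core label; outside both boxes it is
    INTERMEDIARY when it is stranded *between* the groups — its x has
    crossed at least ``gap_margin`` of the horizontal gap separating the two
    boxes (measured from its own group's side) and it lies in the convex
    hull spanned between the whisker-expanded boxes — and keeps its own core
    label otherwise.
    """
    phenos = sorted({s.phenotype for s in summaries})
    if len(phenos) != 2:
        raise ValueError(
            f"intermediary partition needs exactly two phenotype groups, got {phenos}"
        )
    ga, gb = phenos
    by_group = {p: [s for s in summaries if s.phenotype == p] for p in phenos}
    coords = {
        s.promoter_id: np.array(
            [getattr(s, rule.x_axis), getattr(s, rule.y_axis)], dtype=float
        )
        for s in summaries
    }
    core_label = {ga: f"CORE_{ga}", gb: f"CORE_{gb}"}

    # Start with every promoter counted as core for box estimation, then
    # iterate: re-estimate boxes from still-core members only.
    labels = {s.promoter_id: core_label[s.phenotype] for s in summaries}
    boxes: dict[str, tuple[float, float, float, float]] = {}
    for _ in range(max(1, rule.refine_iterations)):
        for p in phenos:
            members = [
                s for s in by_group[p] if labels[s.promoter_id] == core_label[p]
            ]
            if len(members) >= 2 or p not in boxes:
                pts = np.array([coords[s.promoter_id] for s in (members or by_group[p])])
                boxes[p] = _quantile_box(pts, rule, p)

        expanded = {}
        for p in phenos:
            x0, y0, x1, y1 = boxes[p]
            expanded[p] = _expand(
                boxes[p], rule.whisker * (x1 - x0), rule.whisker * (y1 - y0)
            )
        base_geo = {p: shapely_box(*boxes[p]) for p in phenos}
        exp_geo = {p: shapely_box(*expanded[p]) for p in phenos}
        hull = MultiPoint(
            [c for p in phenos for c in exp_geo[p].exterior.coords]
        ).convex_hull
        # horizontal gap between the two base boxes (empty if they overlap
        # on x); each group's stranded region starts gap_margin into the gap
        left, right = sorted(phenos, key=lambda p: boxes[p][0])
        gap = (boxes[left][2], boxes[right][0])
        margin = rule.gap_margin * max(gap[1] - gap[0], 0.0)
        stranded_x = {
            left: (gap[0] + margin, gap[1]),
            right: (gap[0], gap[1] - margin),
        }

        new_labels: dict[str, str] = {}
        for s in summaries:
            pt = Point(*coords[s.promoter_id])
            own, other = s.phenotype, gb if s.phenotype == ga else ga
            in_own = base_geo[own].intersects(pt)
            in_other = base_geo[other].intersects(pt)
            if in_own and in_other:
                new_labels[s.promoter_id] = "INTERMEDIARY"
            elif in_own:
                new_labels[s.promoter_id] = core_label[own]
            elif in_other:
                new_labels[s.promoter_id] = core_label[other]
            elif (
                stranded_x[own][0] < pt.x < stranded_x[own][1]
                and hull.intersects(pt)
            ):
                new_labels[s.promoter_id] = "INTERMEDIARY"
            else:
                new_labels[s.promoter_id] = core_label[own]
        if new_labels == labels:
            break
        labels = new_labels

    return PhenotypePartition(labels=labels, rule_params=rule.to_dict(), boxes=boxes)


def background_distribution(
    records: Sequence[PromoterRecord],
    params: WindowParams = WindowParams(),
) -> list[tuple[str, float, float]]:
    """Center-of-weight point for every record, via the full profile path.

    Returns ``(promoter_id, x, y)`` triples where x is the mean relative
    (C+G)% and y the mean KIC% of the pattern's lines; these are the points
    plotted in genome-wide distribution figures.
    """
    if not records:
        raise ValueError("background_distribution needs at least one record")
    points = []
    for rec in records:
        summary = summarize_promoter(window_profile(rec, params), rec)
        points.append((rec.id, *summary.center_of_weight))
    return points


def plot_distribution(
    points: Sequence[tuple[str, float, float]],
    out_path,
    *,
    overlays: dict[str, Sequence[tuple[str, float, float]]] | None = None,
    gridsize: int = 60,
) -> None:
    """2-D density plot of center-of-weight points with optional panel overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "promarch"}):
        fig, ax = plt.subplots(figsize=(6, 5), dpi=150)
        xs = [p[1] for p in points]
        ys = [p[2] for p in points]
        hb = ax.hexbin(xs, ys, gridsize=gridsize, cmap="jet", mincnt=1)
        fig.colorbar(hb, ax=ax, label="promoters per cell")
        if overlays:
            for label, pts in overlays.items():
                ax.scatter(
                    [p[1] for p in pts],
                    [p[2] for p in pts],
                    s=28,
                    label=label,
                    edgecolor="black",
                    linewidth=0.5,
                    zorder=3,
                )
            ax.legend(frameon=False)
        ax.set_xlabel("center of weight: relative (C+G)%")
        ax.set_ylabel("center of weight: Kappa IC (%)")
        fig.savefig(out_path, metadata={"Date": None} if str(out_path).endswith(".svg") else None)
        plt.close(fig)
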