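"""Composite potency scorecards: z-scaled metrics, radar polygons, group summaries.

Each product is summarized by five metrics — the four effector boolean-gate
signature frequencies (cytotoxicity, activation, infiltration, resilience)
and the 33-day integrated killing value at the 2:1 E:T ratio.  Metrics are
z-scaled across the cohort (sample SD, ddof = 1), mapped to non-negative
radii, and drawn as a radar polygon whose shoelace area (arbitrary units) is
the product's composite potency score: a larger polygon means greater
overall performance.  Area is invariant to cyclic rotation of the axis order
but not to arbitrary permutation, so the axis order is fixed in config and
recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CohortZScaler",
    "zscale_metrics",
    "radial_map",
    "polygon_area",
    "ProductScorecard",
    "build_scorecards",
    "radar_plot",
    "DEFAULT_AXIS_ORDER",
]

DEFAULT_AXIS_ORDER: tuple[str, ...] = (
    "cytotoxicity",
    "activation",
    "infiltration",
    "resilience",
    "serial_killing",
)

# radial floor avoids degenerate zero-radius vertices in the polygon
RADIAL_RANGE: tuple[float, float] = (0.05, 1.0)


class CohortZScaler(TransformerMixin, BaseEstimator):
    """Column-wise z-scaling with the sample standard deviation (ddof = 1).

    Unlike ``StandardScaler`` this uses the unbiased SD, matching the
    convention of cohort-level scorecards with few products.  A zero-SD
    column is an error naming the offending metric.
    """

    def fit(self, X, y=None):
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if Xv.shape[0] < 2:
            raise ValueError("z-scaling requires at least 2 products")
        self.mean_ = Xv.mean(axis=0)
        self.scale_ = Xv.std(axis=0, ddof=1)
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(Xv.shape[1])]
        zero = [n for n, s in zip(names, self.scale_) if s == 0]
        if zero:
            raise ValueError(f"metric(s) with zero standard deviation: {zero}")
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xv.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        if isinstance(X, pd.DataFrame):
            return (X - self.mean_) / self.scale_
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def zscale_metrics(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-scale a products x metrics table column-wise (sample SD, ddof = 1)."""
    return CohortZScaler().fit_transform(matrix)


def radial_map(z: pd.DataFrame, lo: float = RADIAL_RANGE[0], hi: float = RADIAL_RANGE[1]) -> pd.DataFrame:
    """Map z-scores to radar radii: per-axis min-max across the cohort to [lo, hi].

    The floor ``lo > 0`` keeps every vertex off the origin so single-axis
    dominance still contributes area.  Rank order within each axis is
    preserved.
    """
    zmin = z.min(axis=0)
    span = z.max(axis=0) - zmin
    unit = (z - zmin).div(span.where(span > 0, 1.0), axis=1)
    unit.loc[:, span <= 0] = 0.5
    return lo + unit * (hi - lo)


def polygon_area(radii: Sequence[float]) -> float:
    """Shoelace area of the radar polygon with equally spaced axes.

    Vertices sit at ``(r_i cos θ_i, r_i sin θ_i)`` with ``θ_i = 2πi/m``;
    the area reduces to ``0.5 * sin(2π/m) * Σ r_i r_{i+1}`` (cyclic).
    Requires at least 3 axes and non-negative radii.
    """
    r = np.asarray(radii, dtype=float)
    m = len(r)
    if m < 3:
        raise ValueError("polygon needs at least 3 axes")
    if np.any(r < 0):
        raise ValueError("radii must be non-negative after radial mapping")
    return float(0.5 * np.sin(2.0 * np.pi / m) * np.sum(r * np.roll(r, -1)))


@dataclass
class ProductScorecard:
    """Per-product composite potency record."""

    product: str
    group: str
    metrics: dict[str, float]
    z: dict[str, float]
    radii: dict[str, float]
    area: float
    axis_order: tuple[str, ...] = DEFAULT_AXIS_ORDER

    def to_dict(self) -> dict:
        return {
            "product": self.product,
            "group": self.group,
            "metrics": dict(self.metrics),
            "z": dict(self.z),
            "radii": dict(self.radii),
            "area": self.area,
            "axis_order": list(self.axis_order),
        }


def build_scorecards(
    signature_freqs: pd.DataFrame,
    iv33_table: pd.DataFrame,
    groups: Mapping[str, str],
    axis_order: Sequence[str] = DEFAULT_AXIS_ORDER,
    et_ratio: str = "2:1",
) -> tuple[list[ProductScorecard], pd.DataFrame]:
    """Assemble per-product scorecards and the per-group metric summary.

    ``signature_freqs``: products x signature-frequency table (%);
    ``iv33_table``: long table (product, et_ratio, iv33) from which the
    serial-killing axis is taken at ``et_ratio``; ``groups`` maps product ->
    construct group.  Products missing any metric are excluded with a
    warning.  The group summary is the per-metric mean of the raw metrics by
    group.
    """
    killing = (
        iv33_table.loc[iv33_table["et_ratio"] == et_ratio]
        .set_index("product")["iv33"]
        .rename("serial_killing")
    )
    metrics = signature_freqs.join(killing, how="outer")
    incomplete = metrics.index[metrics.isna().any(axis=1)].tolist()
    if incomplete:
        warnings.warn(f"products excluded for missing metrics: {incomplete}", stacklevel=2)
        metrics = metrics.dropna()
    missing_axes = [a for a in axis_order if a not in metrics.columns]
    if missing_axes:
        raise ValueError(f"axis metrics not present: {missing_axes}")
    metrics = metrics[list(axis_order)]

    z = zscale_metrics(metrics)
    radii = radial_map(z)
    cards = []
    for product in metrics.index:
        r = radii.loc[product, list(axis_order)].to_numpy(dtype=float)
        cards.append(
            ProductScorecard(
                product=str(product),
                group=str(groups.get(product, "")),
                metrics=metrics.loc[product].to_dict(),
                z=z.loc[product].to_dict(),
                radii=radii.loc[product].to_dict(),
                area=polygon_area(r),
                axis_order=tuple(axis_order),
            )
        )
    group_summary = metrics.groupby(pd.Series({p: groups.get(p, "") for p in metrics.index})).mean()
    group_summary.index.name = "group"
    return cards, group_summary


def radar_plot(cards: Sequence[ProductScorecard], path, ncols: int = 5) -> None:
    """Radar (spider) charts per product, area annotated; saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(cards)
    ncols = min(ncols, max(n, 1))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows), subplot_kw={"projection": "polar"})
    axes = np.atleast_1d(axes).ravel()
    for ax, card in zip(axes, cards):
        order = list(card.axis_order)
        theta = np.linspace(0, 2 * np.pi, len(order), endpoint=False)
        r = [card.radii[a] for a in order]
        ax.plot(np.r_[theta, theta[0]], np.r_[r, r[0]], lw=1.5)
        ax.fill(np.r_[theta, theta[0]], np.r_[r, r[0]], alpha=0.25)
        ax.set_xticks(theta)
        ax.set_xticklabels(order, fontsize=6)
        ax.set_yticklabels([])
        ax.set_title(f"{card.product} ({card.group})\narea={card.area:.2f}", fontsize=8)
    for ax in axes[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
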