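"""Spatial Gini decomposition of areal inequality and temporal trends.

The classical Gini of a region's values is split exactly into a
neighbor-pair component and a non-neighbor-pair component under a binary
contiguity matrix:

    G = sum_ij w_ij |y_i - y_j| / (2 n^2 ybar)
      + sum_ij (1 - w_ij) |y_i - y_j| / (2 n^2 ybar)

computed within each region (province) and year, with a Mann-Kendall /
Theil-Sen trend verdict per region across years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hotspots import mann_kendall
from .panel import AreaPanel, SpatialWeights


def classical_gini(values) -> float:
    """Gini coefficient G = sum_ij |y_i - y_j| / (2 n^2 ybar), in [0, 1)."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("Gini needs at least 2 values")
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError("Gini undefined for mean <= 0")
    diff = np.abs(y[:, None] - y[None, :]).sum()
    return float(diff / (2 * y.size**2 * ybar))


def spatial_gini_decompose(
    values, weights: SpatialWeights
) -> tuple[float, float, float]:
    """Split the Gini double sum into neighbor and non-neighbor parts.

    Returns (neighbor, non_neighbor, total); the two parts add exactly to
    the classical Gini (the i = j diagonal contributes zero either way).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n != weights.n_areas:
        raise ValueError(f"{n} values but weights cover {weights.n_areas} areas")
    if n < 2:
        raise ValueError("need at least 2 areas")
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError("Gini undefined for mean <= 0")
    denom = 2 * n**2 * ybar
    w = weights.to_sparse().toarray().astype(bool)
    absdiff = np.abs(y[:, None] - y[None, :])
    neighbor = float(absdiff[w].sum() / denom)
    total = float(absdiff.sum() / denom)
    return neighbor, total - neighbor, total


@dataclass
class GiniDecomposition:
    region: str
    year: int
    neighbor: float
    non_neighbor: float
    total: float
    neighbor_share_pct: float
    n_areas: int


def gini_by_region_year(panel: AreaPanel, weights: SpatialWeights) -> pd.DataFrame:
    """One spatial-Gini decomposition per (region, year).

    Only within-region adjacency is used (cross-region borders ignored).
    Singleton regions are skipped with a warning.  Returns a tidy frame
    with columns region, year, neighbor, non_neighbor, total,
    neighbor_share_pct, n_areas, plus a region-level mean via groupby.
    """
    resp = panel.response
    rows = []
    for region, members in panel.regions().items():
        if len(members) < 2:
            warnings.warn(f"region {region} has a single area; skipped", stacklevel=2)
            continue
        sub_w = weights.subset(members)
        for t, year in enumerate(panel.years):
            y = resp[members, t]
            if np.all(y == y[0]):
                nbr = non = tot = 0.0
            else:
                nbr, non, tot = spatial_gini_decompose(y, sub_w)
            share = 100.0 * nbr / tot if tot > 0 else 0.0
            rows.append(
                GiniDecomposition(region, int(year), nbr, non, tot, share, len(members))
            )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class GiniTrend:
    region: str
    slope_per_year: float
    mann_kendall_z: float
    p_value: float
    verdict: str  # decreasing / increasing / none


def gini_trend(series, years=None, alpha: float = 0.05, region: str = "") -> GiniTrend:
    """Mann-Kendall test + Theil-Sen slope on one region's Gini series."""
    y = np.asarray(series, dtype=float)
    if y.size < 4:
        raise ValueError("trend test needs at least 4 years")
    x = np.asarray(years, dtype=float) if years is not None else np.arange(y.size, dtype=float)
    if np.all(y == y[0]):
        return GiniTrend(region, 0.0, 0.0, 1.0, "none")
    _, _, z, p = mann_kendall(y)
    slope = stats.theilslopes(y, x).slope
    if p < alpha and slope < 0:
        verdict = "decreasing"
    elif p < alpha and slope > 0:
        verdict = "increasing"
    else:
        verdict = "none"
    return GiniTrend(region, float(slope), float(z), float(p), verdict)


def region_mean_totals(decompositions: pd.DataFrame) -> pd.DataFrame:
    """Study-period mean total Gini per region (spatial-inequality map analogue)."""
    out = decompositions.groupby("region", as_index=False)["total"].mean()
    return out.rename(columns={"total": "mean_total_gini"})


def gini_trends_by_region(
    decompositions: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Trend verdict of the total spatial Gini per region."""
    rows = []
    for region, grp in decompositions.sort_values("year").groupby("region"):
        tr = gini_trend(grp["total"].to_numpy(), grp["year"].to_numpy(), alpha, region)
        rows.append(tr.__dict__)
    return pd.DataFrame(rows)


def summarize_trend_counts(counts: dict[str, int]) -> dict:
    """Verdict counts -> percentages (denominator: regions with a verdict
    of decreasing or increasing plus none; i.e. all tested regions)."""
    from .hotspots import _round_half_up

    total = sum(int(v) for v in counts.values())
    pct = lambda v: _round_half_up(100.0 * v / total) if total else 0.0
    return {
        "n_regions": total,
        **{
            k: {"count": int(counts.get(k, 0)), "pct": pct(int(counts.get(k, 0)))}
            for k in ("decreasing", "increasing", "none")
        },
    }


def summarize_trends(trends: pd.DataFrame) -> dict:
    counts = trends["verdict"].value_counts().to_dict()
    return summarize_trend_counts(counts)
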