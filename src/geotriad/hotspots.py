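"""Emerging hot/cold spot analysis.

Per-year Getis-Ord Gi* z-scores over the panel, a Mann-Kendall monotone
trend test on each area's z-score series, and a rule-based classification
of areas into trend-aware hot/cold spot categories (new, consecutive,
intensifying, persistent, diminishing, sporadic, oscillating,
historical; hot and cold variants).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AreaPanel, SpatialWeights

Z90, Z95, Z99 = 1.645, 1.96, 2.576

HOT_CATEGORIES = [
    "new hot spot", "consecutive hot spot", "intensifying hot spot",
    "persistent hot spot", "diminishing hot spot", "sporadic hot spot",
    "oscillating hot spot", "historical hot spot",
]
COLD_CATEGORIES = [c.replace("hot", "cold") for c in HOT_CATEGORIES]
NO_PATTERN = "no pattern"


# ---------------------------------------------------------------------------
# Getis-Ord Gi*


def gi_star_slice(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Getis-Ord Gi* z-scores for one cross-section.

    Self-inclusive binary star neighborhood J(i) = neighbors(i) + {i}:

        z_i = (sum_{j in J} y_j - ybar * |J|)
              / (s * sqrt((n*|J| - |J|^2) / (n - 1)))

    with ybar and s the mean and population SD over all n areas.  A
    constant field has s = 0; by convention all z are 0 then (warning).
    """
    y = np.asarray(values, dtype=float)
    n = weights.n_areas
    if y.shape != (n,):
        raise ValueError(f"values length {y.shape} does not match {n} areas")
    if n < 3:
        raise ValueError("Gi* needs at least 3 areas")
    ybar = y.mean()
    s = y.std()  # population SD
    if s == 0:
        warnings.warn("degenerate field (all values equal); Gi* z set to 0", stacklevel=2)
        return np.zeros(n)
    adj = weights.to_sparse()
    star_sum = adj @ y + y
    star_size = weights.degrees() + 1.0
    denom = s * np.sqrt((n * star_size - star_size**2) / (n - 1))
    return (star_sum - ybar * star_size) / denom


@dataclass
class GiStarCube:
    """Per-area, per-year Gi* z-scores with two-sided p-values and
    significance bins (99/95/90% hot, not significant, 90/95/99% cold)."""

    z: np.ndarray  # N x T
    p: np.ndarray  # N x T
    significance: np.ndarray  # N x T object array of bin labels
    temporal_window: int = 0

    @staticmethod
    def _bin(z: float) -> str:
        if z >= Z99:
            return "hot99"
        if z >= Z95:
            return "hot95"
        if z >= Z90:
            return "hot90"
        if z <= -Z99:
            return "cold99"
        if z <= -Z95:
            return "cold95"
        if z <= -Z90:
            return "cold90"
        return "ns"


def gi_star_cube(
    panel_or_values, weights: SpatialWeights, temporal_window: int = 0
) -> GiStarCube:
    """Gi* z-scores for every (area, year).

    ``temporal_window=0`` (default): each year is scored independently
    with the purely spatial statistic.  ``temporal_window=1``: each bin's
    neighborhood also includes the same star set in the adjacent years
    (space-time neighbors), and the mean/SD are taken over all N*T bins.
    """
    values = panel_or_values.response if isinstance(panel_or_values, AreaPanel) else np.asarray(
        panel_or_values, dtype=float
    )
    n, t = values.shape
    if n != weights.n_areas:
        raise ValueError("panel and weights disagree on the number of areas")
    z = np.empty((n, t))
    if temporal_window == 0:
        for tt in range(t):
            z[:, tt] = gi_star_slice(values[:, tt], weights)
    elif temporal_window == 1:
        ntot = n * t
        ybar = values.mean()
        s = values.std()
        if s == 0:
            warnings.warn("degenerate cube (all values equal); Gi* z set to 0", stacklevel=2)
            z[:] = 0.0
        else:
            adj = weights.to_sparse()
            star = adj @ values + values  # spatial star sums per year
            star_size = weights.degrees() + 1.0
            for tt in range(t):
                lo, hi = max(0, tt - 1), min(t - 1, tt + 1)
                wsum = star[:, lo:hi + 1].sum(axis=1)
                size = star_size * (hi - lo + 1)
                denom = s * np.sqrt((ntot * size - size**2) / (ntot - 1))
                z[:, tt] = (wsum - ybar * size) / denom
    else:
        raise ValueError("temporal_window must be 0 or 1")
    p = 2 * stats.norm.sf(np.abs(z))
    sig = np.vectorize(GiStarCube._bin)(z).astype(object)
    return GiStarCube(z=z, p=p, significance=sig, temporal_window=temporal_window)


# ---------------------------------------------------------------------------
# Mann-Kendall


def mann_kendall(series) -> tuple[int, float, float, float]:
    """Mann-Kendall monotone trend test.

    Returns (S, var_S, z, p) with the tie-corrected variance

        var_S = [n(n-1)(2n+5) - sum_ties t(t-1)(2t+5)] / 18

    and the continuity-corrected normal z-score; p is two-sided.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Mann-Kendall needs at least 4 observations")
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2 * stats.norm.sf(abs(z)) if var_s > 0 else 1.0
    return s, var_s, z, p


# ---------------------------------------------------------------------------
# Emerging pattern classification


@dataclass
class PatternResult:
    area_id: str
    category: str
    mk_z: float
    mk_p: float
    hot_count: int
    cold_count: int


def _persistence_threshold(frac: float, t: int) -> int:
    # "at least 9 of 10" style: ceil with guard against float fuzz
    return math.ceil(frac * t - 1e-9)


def _classify_one_sided(
    primary: np.ndarray, opposite: np.ndarray, mk_z: float, mk_p: float,
    alpha: float, recency: int, persistence_frac: float, side: str,
) -> str | None:
    """Apply the rule ladder for one role assignment.

    ``primary``/``opposite`` are boolean per-year significance of the
    spot type being tested / of the opposite type.  ``mk_z`` is oriented
    so positive means the primary intensity is increasing.
    """
    t = len(primary)
    n_primary = int(primary.sum())
    if n_primary == 0:
        return None
    thresh = _persistence_threshold(persistence_frac, t)
    final = bool(primary[-1])
    hot_idx = np.nonzero(primary)[0]
    run_ending_final = final and (np.all(np.diff(hot_idx) == 1) if len(hot_idx) else False)
    mk_sig = mk_p < alpha

    name = lambda cat: f"{cat} {side} spot"
    # 1 NEW: significant only in the final `recency` step(s)
    if final and np.all(hot_idx >= t - recency):
        return name("new")
    # 2 CONSECUTIVE: one unbroken run ending in the final step, < thresh steps
    if run_ending_final and n_primary < thresh:
        return name("consecutive")
    # 3-5 high-persistence categories
    if n_primary >= thresh:
        if final and mk_sig and mk_z > 0:
            return name("intensifying")
        if not mk_sig:
            return name("persistent")
        if mk_sig and mk_z < 0:
            return name("diminishing")
    # 6 SPORADIC: on-and-off, ending significant, never the opposite type
    if final and not run_ending_final and not opposite.any():
        return name("sporadic")
    # 7 OSCILLATING: ends significant with earlier opposite-type history
    if final and opposite[:-1].any():
        return name("oscillating")
    # 8 HISTORICAL: persistent history but not significant in the final step
    if not final and int(primary[:-1].sum()) >= thresh:
        return name("historical")
    return None


def classify_emerging_pattern(
    cube: GiStarCube,
    area_ids: list[str] | None = None,
    alpha: float = 0.05,
    recency: int = 1,
    persistence_frac: float = 0.9,
    fdr: bool = False,
) -> list[PatternResult]:
    """Classify every area's Gi* z series into an emerging pattern category.

    Hot/cold significance per year uses the two-sided alpha z threshold
    (1.96 at alpha = 0.05); ``fdr=True`` instead applies a
    Benjamini-Hochberg correction across areas within each year.  Hot
    rules are evaluated first, then the mirrored cold rules
    (Mann-Kendall orientation flipped), else 'no pattern'.  The
    classifier is total and deterministic.
    """
    z = cube.z
    n, t = z.shape
    if area_ids is None:
        area_ids = [str(i) for i in range(n)]
    zcrit = stats.norm.isf(alpha / 2)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        sig = np.column_stack(
            [multipletests(cube.p[:, tt], alpha=alpha, method="fdr_bh")[0] for tt in range(t)]
        )
        hot_mat = sig & (z > 0)
        cold_mat = sig & (z < 0)
    else:
        hot_mat = z >= zcrit
        cold_mat = z <= -zcrit
    results = []
    for i in range(n):
        hot = hot_mat[i]
        cold = cold_mat[i]
        _, _, mk_z, mk_p = mann_kendall(z[i])
        cat = _classify_one_sided(hot, cold, mk_z, mk_p, alpha, recency, persistence_frac, "hot")
        if cat is None:
            cat = _classify_one_sided(
                cold, hot, -mk_z, mk_p, alpha, recency, persistence_frac, "cold"
            )
        results.append(
            PatternResult(
                area_id=area_ids[i],
                category=cat or NO_PATTERN,
                mk_z=mk_z,
                mk_p=mk_p,
                hot_count=int(hot.sum()),
                cold_count=int(cold.sum()),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Summaries


def _round_half_up(x: float, digits: int = 2) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_pattern_counts(counts: dict[str, int], n_total_areas: int) -> dict:
    """Percentage bookkeeping from per-category counts.

    Percentages of classified areas use the number of patterned areas as
    the denominator; the patterned share itself is over all areas.  All
    percentages are rounded half-up to 2 decimals.
    """
    counts = {c: int(v) for c, v in counts.items() if c != NO_PATTERN and v > 0}
    n_pattern = sum(counts.values())
    n_hot = sum(v for c, v in counts.items() if "hot" in c)
    n_cold = sum(v for c, v in counts.items() if "cold" in c)
    pct = lambda num, den: _round_half_up(100.0 * num / den) if den else 0.0
    per_category = {
        c: {
            "count": v,
            "pct_of_patterned": pct(v, n_pattern),
            "pct_of_all": pct(v, n_total_areas),
        }
        for c, v in sorted(counts.items())
    }
    return {
        "n_areas": n_total_areas,
        "n_patterned": n_pattern,
        "pct_patterned": pct(n_pattern, n_total_areas),
        "n_hot": n_hot,
        "pct_hot_of_patterned": pct(n_hot, n_pattern),
        "n_cold": n_cold,
        "pct_cold_of_patterned": pct(n_cold, n_pattern),
        "categories": per_category,
    }


def summarize_patterns(results: list[PatternResult]) -> dict:
    """Counts and percentages per category over classifier output."""
    counts: dict[str, int] = {}
    for r in results:
        if r.category != NO_PATTERN:
            counts[r.category] = counts.get(r.category, 0) + 1
    return summarize_pattern_counts(counts, len(results))


def patterns_to_dataframe(results: list[PatternResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "area_id": [r.area_id for r in results],
            "category": [r.category for r in results],
            "mk_z": [r.mk_z for r in results],
            "mk_p": [r.mk_p for r in results],
            "hot_count": [r.hot_count for r in results],
            "cold_count": [r.cold_count for r in results],
        }
    )
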