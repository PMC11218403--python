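"""Spatiotemporal variance partitioning index (STVPI).

Each covariate's share of the explainable spatiotemporal variation, on
the standard-deviation scale:

    rho_k = (sigma_mu_k + sigma_gamma_k)
            / (sum_k (sigma_mu_k + sigma_gamma_k) + sigma_eps) * 100%

computed per retained posterior draw (so credible intervals propagate
the joint posterior dependence) and then summarized.  The same
denominator yields per-factor space and time shares, group shares
(socioeconomic vs environmental), scale shares (space vs time), and the
model vs residual split; all shares over a draw sum to 100 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stvc import STVCPosterior


@dataclass
class STVPIResult:
    covariate_names: list[str]
    grouping: dict[str, str]
    draws: pd.DataFrame  # one row per retained draw, one column per share
    summary: pd.DataFrame  # mean + 2.5/97.5% bounds per share

    def share(self, name: str) -> tuple[float, float, float]:
        row = self.summary.loc[name]
        return float(row["mean"]), float(row["lo2.5"]), float(row["hi97.5"])


def stvpi_draws(posterior: STVCPosterior, grouping: dict[str, str]) -> pd.DataFrame:
    """Per-draw percentage shares (columns) for every partition dimension."""
    names = posterior.covariate_names
    missing = [c for c in names if c not in grouping]
    if missing:
        raise ValueError(f"covariates without a group assignment: {missing}")
    sd_mu = posterior.stacked("sd_mu")  # S x K
    sd_gamma = posterior.stacked("sd_gamma")
    sd_eps = posterior.stacked("sd_eps")  # S
    denom = (sd_mu + sd_gamma).sum(axis=1) + sd_eps
    if np.any(denom <= 0):
        raise ValueError("degenerate draw: all SD components zero")
    cols: dict[str, np.ndarray] = {}
    for j, c in enumerate(names):
        cols[f"rho[{c}]"] = 100.0 * (sd_mu[:, j] + sd_gamma[:, j]) / denom
        cols[f"space[{c}]"] = 100.0 * sd_mu[:, j] / denom
        cols[f"time[{c}]"] = 100.0 * sd_gamma[:, j] / denom
    for grp in ("socioeconomic", "environmental"):
        members = [j for j, c in enumerate(names) if grouping[c] == grp]
        cols[f"group[{grp}]"] = (
            100.0 * (sd_mu[:, members] + sd_gamma[:, members]).sum(axis=1) / denom
            if members
            else np.zeros(denom.size)
        )
    cols["scale[space]"] = 100.0 * sd_mu.sum(axis=1) / denom
    cols["scale[time]"] = 100.0 * sd_gamma.sum(axis=1) / denom
    cols["residual"] = 100.0 * sd_eps / denom
    cols["model"] = 100.0 - cols["residual"]
    return pd.DataFrame(cols)


def compute_stvpi(posterior: STVCPosterior, grouping: dict[str, str]) -> STVPIResult:
    """Posterior-mean shares with 2.5/97.5% credible bounds."""
    draws = stvpi_draws(posterior, grouping)
    summary = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "lo2.5": draws.quantile(0.025, axis=0),
            "hi97.5": draws.quantile(0.975, axis=0),
        }
    )
    return STVPIResult(
        covariate_names=list(posterior.covariate_names),
        grouping=dict(grouping),
        draws=draws,
        summary=summary,
    )


def rank_determinants(
    result: STVPIResult, cumulative_threshold: float = 84.0
) -> pd.DataFrame:
    """Shortest prefix of factors (by descending posterior-mean rho)
    whose cumulative share reaches the threshold percentage."""
    import warnings

    rows = []
    for c in result.covariate_names:
        m, lo, hi = result.share(f"rho[{c}]")
        rows.append({"covariate": c, "share_pct": m, "lo2.5": lo, "hi97.5": hi})
    ranked = pd.DataFrame(rows).sort_values("share_pct", ascending=False, kind="stable")
    ranked["cumulative_pct"] = ranked["share_pct"].cumsum()
    model_share = result.share("model")[0]
    if cumulative_threshold > model_share:
        warnings.warn(
            f"threshold {cumulative_threshold}% exceeds the model share "
            f"{model_share:.2f}%; returning all factors",
            stacklevel=2,
        )
        return ranked.reset_index(drop=True)
    cut = int(np.argmax(ranked["cumulative_pct"].to_numpy() >= cumulative_threshold))
    return ranked.iloc[: cut + 1].reset_index(drop=True)
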