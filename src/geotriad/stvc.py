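"""Bayesian spatiotemporally varying coefficient (STVC) model.

Model, for a strictly positive response y over areas i and years t and
standardized covariates x_itk:

    log(y_it) = sum_k (beta_k + mu_ik + gamma_tk) x_itk + eps_it
    mu_.k   ~ intrinsic CAR (ICAR) with SD sigma_mu_k, sum-to-zero
    gamma_.k ~ second-order random walk with SD sigma_gamma_k, sum-to-zero
    eps_it  ~ N(0, sigma_eps^2) iid

The per-covariate coefficient surface splits into a global level beta_k
(flat prior; needed for identifiability once both varying parts are
centered), a spatial field mu (the "space-coefficients", SCs) and a
temporal path gamma (the "time-coefficients", TCs).

Inference is blocked Gibbs with conjugate updates.  Each mu_.k (and
gamma_.k) block is drawn jointly from its Gaussian full conditional and
then restricted to the sum-to-zero subspace by conditioning-by-kriging.
A one-off generalized eigendecomposition of (structure matrix,
likelihood weight diagonal) per covariate makes every sweep O(N^2),
since the conditional precision is a scalar combination of the two
matrices at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .panel import AreaPanel, SpatialWeights


@dataclass
class STVCSpec:
    """Sampler configuration.

    Inverse-gamma(a, b) hyperpriors on all variances; `chains`
    independent chains from overdispersed starts; draws after `burn_in`,
    kept every `thin` iterations.
    """

    covariates: list[str] | None = None  # default: all panel covariates
    include_global_coefficients: bool = True
    hyper_a: float = 1.0
    hyper_b: float = 0.01
    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2000
    thin: int = 3
    standardize: bool = True
    seed: int = 0
    # fixed variance components (validation use): dict with sd_mu, sd_gamma,
    # sd_eps; disables the variance Gibbs steps.
    fix_variances: dict | None = None

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class STVCState:
    """Preprocessed model state (log response, standardized design,
    structure matrices and their generalized eigenbases)."""

    log_y: np.ndarray  # N x T
    x: np.ndarray  # N x T x K, standardized per column if requested
    covariate_names: list[str]
    area_ids: list[str]
    years: np.ndarray
    laplacian: np.ndarray  # D - W  (ICAR structure, rank N-1)
    rw2_penalty: np.ndarray  # D2' D2 (RW2 structure, rank T-2)
    x_mean: np.ndarray
    x_sd: np.ndarray
    spec: STVCSpec
    # per-covariate generalized eigensystems
    mu_eig: list = field(default_factory=list)  # (evals, evecs) of (L, diag(c_mu))
    gamma_eig: list = field(default_factory=list)
    c_mu: np.ndarray = None  # type: ignore  # N x K likelihood weights sum_t x^2
    c_gamma: np.ndarray = None  # type: ignore  # T x K
    xtx: np.ndarray = None  # type: ignore  # K x K for the beta block


def rw2_penalty_matrix(t: int) -> np.ndarray:
    """Second-difference penalty D2'D2 (rank T-2; null space = linear paths)."""
    d2 = np.zeros((t - 2, t))
    for r in range(t - 2):
        d2[r, r : r + 3] = (1.0, -2.0, 1.0)
    return d2.T @ d2


def build_stvc(panel: AreaPanel, weights: SpatialWeights, spec: STVCSpec) -> STVCState:
    """Validate inputs and precompute everything the sampler reuses."""
    y = panel.response
    if np.any(y <= 0):
        bad = np.argwhere(y <= 0)[0]
        raise ValueError(
            f"response must be strictly positive for the log-Gaussian likelihood; "
            f"cell (area {panel.area_ids[bad[0]]}, year {panel.years[bad[1]]}) is not. "
            "Floor the HRDI or exclude the area."
        )
    if len(weights.connected_components()) > 1:
        raise ValueError("spatial graph must be connected for the ICAR prior")
    names = spec.covariates if spec.covariates is not None else list(panel.covariate_names)
    idx = [panel.covariate_names.index(c) for c in names]
    x = panel.covariates[:, :, idx].astype(float).copy()
    n, t, k = x.shape
    if k == 0:
        raise ValueError("need at least one covariate")
    flat = x.reshape(n * t, k)
    x_mean, x_sd = flat.mean(axis=0), flat.std(axis=0)
    if spec.standardize:
        if np.any(x_sd == 0):
            raise ValueError("constant covariate cannot be standardized")
        flat = (flat - x_mean) / x_sd
        x = flat.reshape(n, t, k)

    w = weights.to_sparse().toarray()
    lap = np.diag(w.sum(axis=1)) - w
    rpen = rw2_penalty_matrix(t)

    c_mu = np.einsum("itk,itk->ik", x, x)  # N x K
    c_gamma = np.einsum("itk,itk->tk", x, x)  # T x K
    if np.any(c_mu <= 0) or np.any(c_gamma <= 0):
        raise ValueError("a covariate is identically zero for some area or year")

    state = STVCState(
        log_y=np.log(y),
        x=x,
        covariate_names=list(names),
        area_ids=list(panel.area_ids),
        years=panel.years.copy(),
        laplacian=lap,
        rw2_penalty=rpen,
        x_mean=x_mean,
        x_sd=x_sd,
        spec=spec,
        c_mu=c_mu,
        c_gamma=c_gamma,
        xtx=flat.T @ flat,
    )
    for j in range(k):
        state.mu_eig.append(linalg.eigh(lap, np.diag(c_mu[:, j])))
        state.gamma_eig.append(linalg.eigh(rpen, np.diag(c_gamma[:, j])))
    return state


def _sample_gmrf_block(
    evals: np.ndarray,
    evecs: np.ndarray,
    b: np.ndarray,
    prior_prec: float,
    lik_prec: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from N(Q^-1 b, Q^-1) with Q = prior_prec*S + lik_prec*C, using
    the generalized eigensystem S v = lambda C v (V' C V = I, so
    Q^-1 = V diag(1/d) V' with d = prior_prec*lambda + lik_prec), then
    condition on the sum-to-zero constraint by kriging."""
    d = prior_prec * evals + lik_prec
    vt_b = evecs.T @ b
    draw = evecs @ (vt_b / d + rng.standard_normal(d.size) / np.sqrt(d))
    # condition on 1'x = 0:  x* = x - Q^-1 1 (1' Q^-1 1)^-1 (1' x)
    q1 = evecs @ (evecs.sum(axis=0) / d)
    return draw - q1 * (draw.sum() / q1.sum())


@dataclass
class STVCPosterior:
    """Retained draws (chain-major) and convergence diagnostics.

    Draw arrays have a leading (chains, draws_per_chain) shape; SD-scale
    variance components throughout.
    """

    covariate_names: list[str]
    area_ids: list[str]
    years: np.ndarray
    beta: np.ndarray  # C x S x K
    mu: np.ndarray  # C x S x N x K
    gamma: np.ndarray  # C x S x T x K
    sd_mu: np.ndarray  # C x S x K
    sd_gamma: np.ndarray  # C x S x K
    sd_eps: np.ndarray  # C x S
    fitted: np.ndarray  # N x T posterior-mean fit of log y
    residuals: np.ndarray  # N x T
    rhat: dict
    ess: dict
    converged: bool
    x_mean: np.ndarray
    x_sd: np.ndarray
    standardized: bool

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains flattened into one sample axis."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]


def _diagnostics(samples: dict[str, np.ndarray]) -> tuple[dict, dict, bool]:
    """Split R-hat and bulk ESS per scalar component via arviz."""
    import arviz as az

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name, arr in samples.items():
        # arr: C x S (x K)
        data = az.convert_to_dataset({name: arr})
        r = az.rhat(data)[name].values
        e = az.ess(data)[name].values
        if r.ndim == 0:
            rhat[name] = float(r)
            ess[name] = float(e)
        else:
            for j in range(r.size):
                rhat[f"{name}[{j}]"] = float(r.flat[j])
                ess[f"{name}[{j}]"] = float(e.flat[j])
    bad = [k for k, v in rhat.items() if k.startswith("sd") and v > 1.1]
    return rhat, ess, not bad


def fit_stvc(state: STVCState) -> STVCPosterior:
    """Blocked Gibbs sampler over (mu, gamma, beta, variances)."""
    spec = state.spec
    x, ell = state.x, state.log_y
    n, t, k = x.shape
    a0, b0 = spec.hyper_a, spec.hyper_b
    n_keep = (spec.iterations - spec.burn_in + spec.thin - 1) // spec.thin
    fixed = spec.fix_variances

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    beta_d = np.zeros((spec.chains, n_keep, k))
    mu_d = np.zeros((spec.chains, n_keep, n, k))
    gamma_d = np.zeros((spec.chains, n_keep, t, k))
    sd_mu_d = np.zeros((spec.chains, n_keep, k))
    sd_gamma_d = np.zeros((spec.chains, n_keep, k))
    sd_eps_d = np.zeros((spec.chains, n_keep))

    xtx_chol = linalg.cho_factor(state.xtx)
    beta_cov_chol = linalg.cholesky(np.linalg.inv(state.xtx), lower=True)

    for c in range(spec.chains):
        rng = np.random.default_rng(seeds[c])
        # overdispersed starts
        mu = 0.1 * rng.standard_normal((n, k))
        mu -= mu.mean(axis=0)
        gamma = 0.1 * rng.standard_normal((t, k))
        gamma -= gamma.mean(axis=0)
        beta = rng.standard_normal(k) if spec.include_global_coefficients else np.zeros(k)
        if fixed is not None:
            var_mu = np.asarray(fixed["sd_mu"], dtype=float) ** 2
            var_gamma = np.asarray(fixed["sd_gamma"], dtype=float) ** 2
            var_eps = float(fixed["sd_eps"]) ** 2
        else:
            var_mu = np.exp(rng.uniform(-2, 1, k))
            var_gamma = np.exp(rng.uniform(-2, 1, k))
            var_eps = float(np.exp(rng.uniform(-2, 1)))

        contrib_mu = mu[:, None, :] * x  # N x T x K
        contrib_gamma = gamma[None, :, :] * x
        fit = x @ beta + contrib_mu.sum(axis=2) + contrib_gamma.sum(axis=2)

        kept = 0
        for it in range(spec.iterations):
            # --- spatial coefficient fields
            for j in range(k):
                r = ell - fit + contrib_mu[:, :, j]
                b = np.einsum("it,it->i", x[:, :, j], r) / var_eps
                mu[:, j] = _sample_gmrf_block(
                    *state.mu_eig[j], b, 1.0 / var_mu[j], 1.0 / var_eps, rng
                )
                new_c = mu[:, j][:, None] * x[:, :, j]
                fit += new_c - contrib_mu[:, :, j]
                contrib_mu[:, :, j] = new_c
            # --- temporal coefficient paths
            for j in range(k):
                r = ell - fit + contrib_gamma[:, :, j]
                b = np.einsum("it,it->t", x[:, :, j], r) / var_eps
                gamma[:, j] = _sample_gmrf_block(
                    *state.gamma_eig[j], b, 1.0 / var_gamma[j], 1.0 / var_eps, rng
                )
                new_c = gamma[:, j][None, :] * x[:, :, j]
                fit += new_c - contrib_gamma[:, :, j]
                contrib_gamma[:, :, j] = new_c
            # --- global coefficients (flat prior)
            if spec.include_global_coefficients:
                r = ell - fit + x @ beta
                bvec = np.einsum("itk,it->k", x, r)
                mean = linalg.cho_solve(xtx_chol, bvec)
                new_beta = mean + np.sqrt(var_eps) * (
                    beta_cov_chol @ rng.standard_normal(k)
                )
                fit += x @ new_beta - x @ beta
                beta = new_beta
            # --- variance components (conjugate inverse-gamma)
            if fixed is None:
                for j in range(k):
                    q = float(mu[:, j] @ state.laplacian @ mu[:, j])
                    var_mu[j] = 1.0 / rng.gamma(a0 + (n - 1) / 2, 1.0 / (b0 + q / 2))
                    q = float(gamma[:, j] @ state.rw2_penalty @ gamma[:, j])
                    var_gamma[j] = 1.0 / rng.gamma(a0 + (t - 2) / 2, 1.0 / (b0 + q / 2))
                resid = ell - fit
                var_eps = 1.0 / rng.gamma(
                    a0 + n * t / 2, 1.0 / (b0 + float((resid**2).sum()) / 2)
                )
            # --- retain
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                beta_d[c, kept] = beta
                mu_d[c, kept] = mu
                gamma_d[c, kept] = gamma
                sd_mu_d[c, kept] = np.sqrt(var_mu)
                sd_gamma_d[c, kept] = np.sqrt(var_gamma)
                sd_eps_d[c, kept] = np.sqrt(var_eps)
                kept += 1

    # posterior-mean fit and residuals
    mean_beta = beta_d.mean(axis=(0, 1))
    mean_mu = mu_d.mean(axis=(0, 1))
    mean_gamma = gamma_d.mean(axis=(0, 1))
    coef = mean_beta[None, None, :] + mean_mu[:, None, :] + mean_gamma[None, :, :]
    fitted = np.einsum("itk,itk->it", coef, x)

    diag_samples = {"sd_eps": sd_eps_d, "sd_mu": sd_mu_d, "sd_gamma": sd_gamma_d}
    if spec.include_global_coefficients:
        diag_samples["beta"] = beta_d
    if spec.chains >= 2 and n_keep >= 4 and fixed is None:
        rhat, ess, converged = _diagnostics(diag_samples)
    else:
        rhat, ess, converged = {}, {}, True
    if not converged:
        warnings.warn(
            "variance-component R-hat exceeds 1.1; posterior flagged non-converged",
            stacklevel=2,
        )
    return STVCPosterior(
        covariate_names=state.covariate_names,
        area_ids=state.area_ids,
        years=state.years,
        beta=beta_d,
        mu=mu_d,
        gamma=gamma_d,
        sd_mu=sd_mu_d,
        sd_gamma=sd_gamma_d,
        sd_eps=sd_eps_d,
        fitted=fitted,
        residuals=state.log_y - fitted,
        rhat=rhat,
        ess=ess,
        converged=converged,
        x_mean=state.x_mean,
        x_sd=state.x_sd,
        standardized=spec.standardize,
    )


QUANTS = (0.025, 0.25, 0.5, 0.75, 0.975)


def extract_sc_tc(posterior: STVCPosterior, centered: bool = False):
    """Posterior quantile tables of the space- and time-coefficients.

    By default the total local effect is reported (beta_k + mu_ik for
    SCs, beta_k + gamma_tk for TCs); ``centered=True`` reports the
    centered varying components alone.  Returns (sc, tc) DataFrames with
    2.5/25/50/75/97.5 percent quantile columns per covariate.
    """
    import pandas as pd

    beta = posterior.stacked("beta")  # S x K
    mu = posterior.stacked("mu")  # S x N x K
    gamma = posterior.stacked("gamma")  # S x T x K
    if not centered:
        mu = mu + beta[:, None, :]
        gamma = gamma + beta[:, None, :]

    def table(draws, keys, key_name):
        qs = np.quantile(draws, QUANTS, axis=0)  # 5 x len(keys) x K
        rows = []
        for e, key in enumerate(keys):
            for j, cov in enumerate(posterior.covariate_names):
                rows.append(
                    {key_name: key, "covariate": cov}
                    | {f"q{int(1000*q)/10:g}": qs[qi, e, j] for qi, q in enumerate(QUANTS)}
                )
        return pd.DataFrame(rows)

    sc = table(mu, posterior.area_ids, "area_id")
    tc = table(gamma, [int(y) for y in posterior.years], "year")
    return sc, tc
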