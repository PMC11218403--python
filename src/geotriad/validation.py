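"""Exact Gaussian posterior for the STVC model with fixed variances.

With the variance components held fixed, the joint of (beta, mu, gamma)
given the data is Gaussian.  This module computes its mean by one dense
linear solve over an explicit design matrix built on orthonormal
sum-to-zero bases — a deliberately direct construction, independent of
the Gibbs sampler's incremental-residual code path, used to validate the
sampler on tiny instances.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .stvc import STVCState


def _sum_zero_basis(m: int) -> np.ndarray:
    """Orthonormal basis (m x (m-1)) of the subspace {x : sum(x) = 0}."""
    return linalg.null_space(np.ones((1, m)))


def exact_posterior_mean(
    state: STVCState, sd_mu, sd_gamma, sd_eps: float
) -> dict[str, np.ndarray]:
    """Posterior mean of (beta, mu, gamma) under fixed variance components.

    Parameterizes mu_.k = B_mu u_k and gamma_.k = B_gamma v_k on
    orthonormal sum-to-zero bases, assembles the full NT x P design, and
    solves (P_prior + Z'Z/sigma_eps^2) theta = Z'ell / sigma_eps^2.
    """
    x, ell = state.x, state.log_y
    n, t, k = x.shape
    sd_mu = np.broadcast_to(np.asarray(sd_mu, dtype=float), (k,))
    sd_gamma = np.broadcast_to(np.asarray(sd_gamma, dtype=float), (k,))

    b_mu = _sum_zero_basis(n)  # N x (N-1)
    b_ga = _sum_zero_basis(t)  # T x (T-1)

    cols = []
    prior_blocks = []
    # beta columns (flat prior)
    for j in range(k):
        cols.append(x[:, :, j].reshape(n * t, 1))
        prior_blocks.append(np.zeros((1, 1)))
    # mu columns: x_itk * B_mu[i, :]
    for j in range(k):
        block = x[:, :, j].reshape(n * t, 1) * np.repeat(b_mu, t, axis=0)
        cols.append(block)
        prior_blocks.append((b_mu.T @ state.laplacian @ b_mu) / sd_mu[j] ** 2)
    # gamma columns: x_itk * B_gamma[t, :]
    for j in range(k):
        block = x[:, :, j].reshape(n * t, 1) * np.tile(b_ga, (n, 1))
        cols.append(block)
        prior_blocks.append((b_ga.T @ state.rw2_penalty @ b_ga) / sd_gamma[j] ** 2)

    z = np.hstack(cols)
    prior = linalg.block_diag(*prior_blocks)
    q = prior + (z.T @ z) / sd_eps**2
    theta = np.linalg.solve(q, z.T @ ell.reshape(n * t) / sd_eps**2)

    beta = theta[:k]
    off = k
    mu = np.column_stack(
        [b_mu @ theta[off + j * (n - 1) : off + (j + 1) * (n - 1)] for j in range(k)]
    )
    off += k * (n - 1)
    gamma = np.column_stack(
        [b_ga @ theta[off + j * (t - 1) : off + (j + 1) * (t - 1)] for j in range(k)]
    )
    return {"beta": beta, "mu": mu, "gamma": gamma}
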