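"""Seedable synthetic areal panels with the generative structure the
downstream analyses assume.

The generator draws, per covariate, a spatial coefficient field from the
intrinsic CAR (ICAR) prior on a contiguity lattice and a temporal
coefficient path from a second-order random walk (RW2), builds
log y_it = sum_k (beta_k + mu_ik + gamma_tk) x_itk + eps_it, and
back-solves a bed count so that the HRDI of the fabricated
population/area fields reproduces y exactly.  Regions are contiguous
square blocks of the lattice, mimicking provinces of counties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import AreaPanel, SpatialWeights, beds_from_hrdi


@dataclass
class SimulationConfig:
    grid_rows: int = 15
    grid_cols: int = 15
    n_years: int = 10
    n_covariates: int = 3
    contiguity: str = "rook"  # or "queen"
    region_blocks: int = 3  # regions form a region_blocks x region_blocks partition
    sd_mu: tuple = (0.5, 0.5, 0.5)  # ICAR field SDs, one per covariate
    sd_gamma: tuple = (0.3, 0.3, 0.3)  # RW2 innovation SDs
    beta: tuple = (1.0, 0.5, -0.5)  # global coefficient levels
    sd_eps: float = 0.2
    covariate_model: str = "spatially_smoothed"  # or "iid_normal"
    socioeconomic: tuple = None  # type: ignore[assignment]  # names in the socioeconomic group
    seed: int = 0

    def __post_init__(self):
        n = self.grid_rows * self.grid_cols
        if n < 9:
            raise ValueError("lattice must have at least 9 cells")
        if self.n_years < 4:
            raise ValueError("need at least 4 years (RW2 requires >= 3 increments)")
        k = self.n_covariates
        for name in ("sd_mu", "sd_gamma", "beta"):
            v = getattr(self, name)
            if np.isscalar(v):
                v = (float(v),) * k
            v = tuple(float(x) for x in v)
            if len(v) != k:
                raise ValueError(f"{name} must have length {k}")
            setattr(self, name, v)
        if any(s < 0 for s in self.sd_mu) or any(s < 0 for s in self.sd_gamma) or self.sd_eps < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.contiguity not in ("rook", "queen"):
            raise ValueError("contiguity must be 'rook' or 'queen'")
        if self.covariate_model not in ("iid_normal", "spatially_smoothed"):
            raise ValueError("unknown covariate_model")

    @property
    def covariate_names(self) -> list[str]:
        return [f"X{j+1}" for j in range(self.n_covariates)]


def make_lattice_weights(rows: int, cols: int, contiguity: str = "rook") -> SpatialWeights:
    """Binary contiguity on a rows x cols lattice (row-major indexing)."""
    if rows < 2 or cols < 2:
        raise ValueError("lattice needs rows, cols >= 2")
    if contiguity == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif contiguity == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError("contiguity must be 'rook' or 'queen'")
    sets: list[set[int]] = []
    for r in range(rows):
        for c in range(cols):
            s = set()
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    s.add(rr * cols + cc)
            sets.append(s)
    return SpatialWeights(rows * cols, sets)


def block_regions(rows: int, cols: int, blocks: int) -> list[str]:
    """Partition the lattice into a blocks x blocks grid of contiguous regions.

    Returns the region label of each cell in row-major order; labels are
    'R00', 'R01', ... by block row/column.
    """
    row_edges = np.linspace(0, rows, blocks + 1)
    col_edges = np.linspace(0, cols, blocks + 1)
    labels = []
    for r in range(rows):
        br = min(int(np.searchsorted(row_edges, r, side="right")) - 1, blocks - 1)
        for c in range(cols):
            bc = min(int(np.searchsorted(col_edges, c, side="right")) - 1, blocks - 1)
            labels.append(f"R{br}{bc}")
    return labels


def _icar_eigenbasis(weights: SpatialWeights):
    """Eigendecomposition of the graph Laplacian D - W restricted to the
    sum-to-zero subspace (the ICAR structure matrix has rank N-1 on a
    connected graph)."""
    comps = weights.connected_components()
    if len(comps) > 1:
        sizes = [len(c) for c in comps]
        raise ValueError(
            f"graph is disconnected ({len(comps)} components of sizes {sizes}); "
            "the intrinsic CAR field is only defined on a connected graph"
        )
    w = weights.to_sparse().toarray()
    lap = np.diag(w.sum(axis=1)) - w
    evals, evecs = np.linalg.eigh(lap)
    # drop the (single) zero eigenvalue / constant eigenvector
    return evals[1:], evecs[:, 1:]


def simulate_icar_field(
    weights: SpatialWeights, sd: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw one field from the intrinsic CAR prior with marginal structure
    sd^2 * pinv(D - W), restricted to the sum-to-zero subspace.

    The draw is sum(field) = 0 by construction (up to rounding).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sd < 0:
        raise ValueError("sd must be >= 0")
    n = weights.n_areas
    if sd == 0:
        return np.zeros(n)
    evals, evecs = _icar_eigenbasis(weights)
    z = rng.standard_normal(n - 1)
    return sd * (evecs @ (z / np.sqrt(evals)))


def simulate_rw2_path(n_years: int, sd: float, rng: np.random.Generator | int) -> np.ndarray:
    """Draw a second-order random-walk path, centered to sum to zero.

    Second differences gamma_t - 2*gamma_{t-1} + gamma_{t-2} are iid
    N(0, sd^2); the level (and only the level) is removed by centering,
    so a linear trend remains expressible (RW2 null space).
    """
    if n_years < 4:
        raise ValueError("RW2 path needs at least 4 years")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    path = np.zeros(n_years)
    innovations = sd * rng.standard_normal(n_years - 2)
    for t in range(2, n_years):
        path[t] = 2 * path[t - 1] - path[t - 2] + innovations[t - 2]
    return path - path.mean()


def _simulate_covariates(cfg: SimulationConfig, weights: SpatialWeights, rng) -> np.ndarray:
    """N x T x K covariates; standardized to mean 0, SD 1 per covariate."""
    n = weights.n_areas
    t, k = cfg.n_years, cfg.n_covariates
    x = rng.standard_normal((n, t, k))
    if cfg.covariate_model == "spatially_smoothed":
        # one-step neighborhood averaging induces positive spatial correlation
        adj = weights.to_sparse()
        deg = np.maximum(weights.degrees(), 1)
        for j in range(k):
            smooth = (adj @ x[:, :, j]) / deg[:, None]
            x[:, :, j] = 0.5 * x[:, :, j] + 0.5 * smooth
    flat = x.reshape(n * t, k)
    flat = (flat - flat.mean(axis=0)) / flat.std(axis=0)
    return flat.reshape(n, t, k)


def simulate_panel(cfg: SimulationConfig) -> tuple[AreaPanel, SpatialWeights, dict]:
    """Generate (AreaPanel, SpatialWeights, truth bundle) from the config.

    The truth bundle holds the drawn beta, mu (N x K), gamma (T x K),
    eps (N x T) and the configured SDs, for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    weights = make_lattice_weights(cfg.grid_rows, cfg.grid_cols, cfg.contiguity)
    n, t, k = weights.n_areas, cfg.n_years, cfg.n_covariates

    x = _simulate_covariates(cfg, weights, rng)
    mu = np.column_stack([simulate_icar_field(weights, cfg.sd_mu[j], rng) for j in range(k)])
    gamma = np.column_stack([simulate_rw2_path(t, cfg.sd_gamma[j], rng) for j in range(k)])
    eps = cfg.sd_eps * rng.standard_normal((n, t))
    beta = np.asarray(cfg.beta)

    coef = beta[None, None, :] + mu[:, None, :] + gamma[None, :, :]  # N x T x K
    log_y = np.einsum("itk,itk->it", coef, x) + eps
    if not np.all(np.isfinite(log_y)) or np.max(log_y) > 300:
        raise ValueError(
            "simulated log-response overflows exp(); use smaller coefficient SDs"
        )
    y = np.exp(log_y)

    population = np.exp(rng.normal(11.0, 0.4, size=(n, t)))  # ~60k persons per county
    land_area = np.exp(rng.normal(7.0, 0.5, size=n))  # ~1100 km^2
    beds = beds_from_hrdi(y, population, land_area[:, None])

    area_ids = [f"A{i:04d}" for i in range(n)]
    labels = block_regions(cfg.grid_rows, cfg.grid_cols, cfg.region_blocks)
    region_of = {a: labels[i] for i, a in enumerate(area_ids)}
    names = cfg.covariate_names
    socio = set(cfg.socioeconomic) if cfg.socioeconomic is not None else set(names[: (k + 1) // 2])
    groups = {c: ("socioeconomic" if c in socio else "environmental") for c in names}

    panel = AreaPanel(
        area_ids=area_ids,
        region_of=region_of,
        years=np.arange(2002, 2002 + t),
        beds=beds,
        population=population,
        land_area=land_area,
        covariates=x,
        covariate_names=names,
        covariate_group=groups,
        response_kind="hrdi",
    )
    truth = {
        "beta": beta,
        "mu": mu,
        "gamma": gamma,
        "eps": eps,
        "sd_mu": np.asarray(cfg.sd_mu),
        "sd_gamma": np.asarray(cfg.sd_gamma),
        "sd_eps": cfg.sd_eps,
        "response": y,
    }
    return panel, weights, truth


# ---------------------------------------------------------------------------
# Deterministic hot/cold spot fixture


def hotspot_preset(seed: int = 0) -> tuple[AreaPanel, SpatialWeights, dict[str, list[int]]]:
    """A 12x12 rook panel (T=10) engineered to exercise the emerging
    hot/cold spot classifier deterministically.

    Because the Gi* z-score is scale invariant, a lone plateau cannot
    intensify: its own amplitude dominates the cross-sectional SD and
    its z-score saturates.  The preset therefore injects four 4x4
    blocks into a low-noise background so each block's prominence is
    measured against the others:

    * a block ramping up year on year relative to the rest
      (designed category: intensifying hot spot),
    * a block of constant amplitude whose relative prominence declines
      as the others grow (diminishing hot spot),
    * a block high only in the final year (new hot spot),
    * a block low from the fifth year onward, 6 of 10 steps
      (consecutive cold spot).

    Returns (panel, weights, designed) where ``designed`` maps category
    name to the list of asserted area indices — the 2x2 interior of
    each block, whose star neighborhoods lie fully inside it.
    """
    rows = cols = 12
    t = 10
    rng = np.random.default_rng(seed)
    weights = make_lattice_weights(rows, cols, "rook")
    n = rows * cols

    base = 20.0 + 0.4 * rng.standard_normal((n, t))

    def block(r0, c0, size=4):
        return [r * cols + c for r in range(r0, r0 + size) for c in range(c0, c0 + size)]

    def interior(r0, c0):
        return [r * cols + c for r in range(r0 + 1, r0 + 3) for c in range(c0 + 1, c0 + 3)]

    intens, new, coldblk, dimin = block(1, 1), block(1, 7), block(7, 1), block(7, 7)
    base[intens, :] += 4.0 + np.arange(t)  # ramping prominence
    base[dimin, :] += 10.0  # constant amplitude, relatively declining
    base[new, -1] += 10.0  # final-year spike
    base[coldblk, 4:] -= 10.0  # low from year index 4 onward

    values = np.maximum(base, 0.1)
    population = np.full((n, t), 50_000.0)
    land_area = np.full(n, 1000.0)
    beds = beds_from_hrdi(values, population, land_area[:, None])
    area_ids = [f"A{i:04d}" for i in range(n)]
    labels = block_regions(rows, cols, 2)
    panel = AreaPanel(
        area_ids=area_ids,
        region_of={a: labels[i] for i, a in enumerate(area_ids)},
        years=np.arange(2002, 2002 + t),
        beds=beds,
        population=population,
        land_area=land_area,
        covariates=np.zeros((n, t, 1)),
        covariate_names=["X1"],
        covariate_group={"X1": "socioeconomic"},
        response_kind="hrdi",
    )
    designed = {
        "intensifying hot spot": interior(1, 1),
        "new hot spot": interior(1, 7),
        "consecutive cold spot": interior(7, 1),
        "diminishing hot spot": interior(7, 7),
    }
    return panel, weights, designed
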