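"""Areal panel data model, file I/O, HRDI construction and VIF screening.

The panel is a balanced N (areas) x T (years) table of a health-resource
count (hospital beds), population, land area and K candidate covariates,
with every area assigned to a region (province).  The response used
downstream is either the raw bed count or the health resource density
index (HRDI), the geometric mean of beds per 1000 population and beds
per square kilometre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PanelValidationError(ValueError):
    """Raised when an input violates a panel or weights invariant."""


# ---------------------------------------------------------------------------
# Spatial weights


@dataclass
class SpatialWeights:
    """Symmetric binary contiguity over areas.

    neighbor_sets[i] is the set of integer indices adjacent to area i;
    the diagonal is always empty.  ``ids`` carries the external labels
    used in GAL files (defaults to stringified indices).
    """

    n_areas: int
    neighbor_sets: list[set[int]]
    ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.ids is None:
            self.ids = [str(i) for i in range(self.n_areas)]
        if len(self.neighbor_sets) != self.n_areas:
            raise PanelValidationError(
                f"neighbor_sets length {len(self.neighbor_sets)} != n_areas {self.n_areas}"
            )
        self.validate()

    def validate(self) -> None:
        for i, nbrs in enumerate(self.neighbor_sets):
            if i in nbrs:
                raise PanelValidationError(f"area {self.ids[i]} lists itself as neighbor")
            for j in nbrs:
                if not (0 <= j < self.n_areas):
                    raise PanelValidationError(f"unknown neighbor index {j} for area {self.ids[i]}")
                if i not in self.neighbor_sets[j]:
                    raise PanelValidationError(
                        f"asymmetric adjacency: {self.ids[i]} -> {self.ids[j]} "
                        f"declared but not {self.ids[j]} -> {self.ids[i]}"
                    )

    @property
    def is_symmetric(self) -> bool:
        return True  # enforced at construction

    def to_sparse(self):
        """Binary adjacency as a scipy CSR matrix."""
        from scipy import sparse

        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbor_sets):
            for j in nbrs:
                rows.append(i)
                cols.append(j)
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self.neighbor_sets])

    def subset(self, indices: list[int]) -> "SpatialWeights":
        """Restrict to the given areas (induced subgraph), reindexed 0..m-1."""
        pos = {a: p for p, a in enumerate(indices)}
        sets = [{pos[j] for j in self.neighbor_sets[a] if j in pos} for a in indices]
        return SpatialWeights(len(indices), sets, ids=[self.ids[a] for a in indices])

    def connected_components(self) -> list[list[int]]:
        seen = np.zeros(self.n_areas, dtype=bool)
        comps = []
        for start in range(self.n_areas):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in self.neighbor_sets[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            comps.append(sorted(comp))
        return comps


def read_gal(path) -> SpatialWeights:
    """Read a GAL contiguity file.

    Format: a header line whose last relevant token is the area count
    (a leading "0" flag as written by some tools is tolerated), then for
    each area a line ``id degree`` followed by a line of neighbor ids.
    """
    with open(path) as fh:
        tokens_header = fh.readline().split()
        if not tokens_header:
            raise PanelValidationError("empty GAL file")
        if len(tokens_header) > 1 and tokens_header[0] == "0":
            n = int(tokens_header[1])
        else:
            n = int(tokens_header[0])
        ids: list[str] = []
        raw_neighbors: dict[str, list[str]] = {}
        for _ in range(n):
            head = fh.readline().split()
            if len(head) != 2:
                raise PanelValidationError(f"malformed GAL record header: {head}")
            area_id, degree = head[0], int(head[1])
            nbr_line = fh.readline().split() if degree > 0 else []
            if degree > 0 and len(nbr_line) != degree:
                raise PanelValidationError(
                    f"area {area_id}: declared degree {degree}, found {len(nbr_line)} neighbors"
                )
            ids.append(area_id)
            raw_neighbors[area_id] = nbr_line
    index = {a: i for i, a in enumerate(ids)}
    sets: list[set[int]] = []
    for a in ids:
        s = set()
        for b in raw_neighbors[a]:
            if b not in index:
                raise PanelValidationError(f"area {a} lists unknown neighbor id {b}")
            s.add(index[b])
        sets.append(s)
    return SpatialWeights(n, sets, ids=ids)


def write_gal(weights: SpatialWeights, path) -> None:
    """Write weights in GAL format; ``write_gal`` then ``read_gal`` is identity."""
    with open(path, "w") as fh:
        fh.write(f"{weights.n_areas}\n")
        for i in range(weights.n_areas):
            nbrs = sorted(weights.neighbor_sets[i])
            fh.write(f"{weights.ids[i]} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(weights.ids[j] for j in nbrs) + "\n")


# ---------------------------------------------------------------------------
# Area panel


@dataclass
class AreaPanel:
    """Balanced areal panel.

    Arrays are area-major: ``response[i, t]`` is area ``area_ids[i]`` in
    year ``years[t]``.  ``covariates`` has shape (N, T, K).
    """

    area_ids: list[str]
    region_of: dict[str, str]
    years: np.ndarray
    beds: np.ndarray  # N x T, raw resource counts
    population: np.ndarray  # N x T, persons
    land_area: np.ndarray  # N, km^2
    covariates: np.ndarray  # N x T x K
    covariate_names: list[str]
    covariate_group: dict[str, str]  # name -> {socioeconomic, environmental}
    response_kind: str = "hrdi"  # or "beds"

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.beds = np.asarray(self.beds, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        self.land_area = np.asarray(self.land_area, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.validate()

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def response(self) -> np.ndarray:
        """Response per config: HRDI (default) or raw beds."""
        if self.response_kind == "beds":
            return self.beds
        return compute_hrdi(self.beds, self.population, self.land_area[:, None])

    def validate(self) -> None:
        n, t, k = len(self.area_ids), len(self.years), len(self.covariate_names)
        if len(set(self.area_ids)) != n:
            raise PanelValidationError("duplicate area ids")
        if len(set(self.covariate_names)) != k:
            raise PanelValidationError("covariate names not unique")
        for arr, shape, name in [
            (self.beds, (n, t), "beds"),
            (self.population, (n, t), "population"),
            (self.land_area, (n,), "land_area"),
            (self.covariates, (n, t, k), "covariates"),
        ]:
            if arr.shape != shape:
                raise PanelValidationError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.population <= 0):
            raise PanelValidationError("population must be strictly positive")
        if np.any(self.land_area <= 0):
            raise PanelValidationError("land_area must be strictly positive")
        if np.any(self.beds < 0):
            raise PanelValidationError("beds must be non-negative")
        missing = [a for a in self.area_ids if a not in self.region_of]
        if missing:
            raise PanelValidationError(f"areas without region assignment: {missing[:5]}")
        for c in self.covariate_names:
            if self.covariate_group.get(c) not in ("socioeconomic", "environmental"):
                raise PanelValidationError(
                    f"covariate {c!r} must be assigned to exactly one of "
                    "{'socioeconomic', 'environmental'}"
                )
        if self.response_kind not in ("hrdi", "beds"):
            raise PanelValidationError(f"unknown response_kind {self.response_kind!r}")

    def regions(self) -> dict[str, list[int]]:
        """Region id -> sorted list of member area indices."""
        out: dict[str, list[int]] = {}
        for i, a in enumerate(self.area_ids):
            out.setdefault(self.region_of[a], []).append(i)
        return {r: sorted(v) for r, v in sorted(out.items())}

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table, one row per (area, year)."""
        n, t = self.n_areas, self.n_years
        rows = {
            "area_id": np.repeat(self.area_ids, t),
            "region_id": np.repeat([self.region_of[a] for a in self.area_ids], t),
            "year": np.tile(self.years, n),
            "beds": self.beds.ravel(),
            "population": self.population.ravel(),
            "land_area": np.repeat(self.land_area, t),
        }
        for k, name in enumerate(self.covariate_names):
            rows[name] = self.covariates[:, :, k].ravel()
        return pd.DataFrame(rows)


DEFAULT_SCHEMA = {
    "area_id": "area_id",
    "region_id": "region_id",
    "year": "year",
    "beds": "beds",
    "population": "population",
    "land_area": "land_area",
}


def read_panel_csv(
    path,
    schema: dict | None = None,
    covariate_columns: list[str] | None = None,
    covariate_group: dict[str, str] | None = None,
    response: str = "hrdi",
) -> AreaPanel:
    """Read a long CSV (one row per area-year) into a validated AreaPanel.

    Columns not in the schema and not listed as covariates are ignored.
    Covariates default to every column prefixed ``X`` and to the
    socioeconomic group unless ``covariate_group`` says otherwise.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(
        path,
        dtype={sch["area_id"]: str, sch["region_id"]: str},
        float_precision="round_trip",
    )
    required = [sch[c] for c in ("area_id", "region_id", "year", "beds", "population", "land_area")]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"missing required columns: {missing_cols}")
    if covariate_columns is None:
        covariate_columns = [c for c in df.columns if c not in required and c.startswith("X")]

    area_ids = sorted(df[sch["area_id"]].unique())
    years = np.array(sorted(df[sch["year"]].unique()))
    n, t = len(area_ids), len(years)

    key = df.set_index([sch["area_id"], sch["year"]])
    if key.index.has_duplicates:
        dup = key.index[key.index.duplicated()][0]
        raise PanelValidationError(f"duplicate (area, year) cell {dup}")
    if len(df) != n * t:
        present = set(key.index)
        for a in area_ids:
            for y in years:
                if (a, y) not in present:
                    raise PanelValidationError(f"unbalanced panel: missing cell (area={a}, year={y})")

    key = key.sort_index()
    beds = key[sch["beds"]].to_numpy(dtype=float).reshape(n, t)
    population = key[sch["population"]].to_numpy(dtype=float).reshape(n, t)
    land_full = key[sch["land_area"]].to_numpy(dtype=float).reshape(n, t)
    if np.any(land_full != land_full[:, [0]]):
        raise PanelValidationError("land_area varies within an area across years")
    region_long = key[sch["region_id"]].to_numpy().reshape(n, t)
    region_of = {a: str(region_long[i, 0]) for i, a in enumerate(area_ids)}
    cov = np.stack(
        [key[c].to_numpy(dtype=float).reshape(n, t) for c in covariate_columns], axis=2
    ) if covariate_columns else np.zeros((n, t, 0))
    groups = {c: (covariate_group or {}).get(c, "socioeconomic") for c in covariate_columns}
    return AreaPanel(
        area_ids=area_ids,
        region_of=region_of,
        years=years,
        beds=beds,
        population=population,
        land_area=land_full[:, 0],
        covariates=cov,
        covariate_names=list(covariate_columns),
        covariate_group=groups,
        response_kind=response,
    )


def write_panel_csv(panel: AreaPanel, path) -> None:
    """Write the long-form CSV; read_panel_csv round-trips all numeric fields."""
    df = panel.to_dataframe()
    # repr-precision floats so write -> read is bit-exact
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# HRDI


def compute_hrdi(beds, population, land_area):
    """Health resource density index.

    Geometric mean of beds per 1000 population and beds per km^2:
    sqrt((beds / (population/1000)) * (beds / land_area)).  Vectorized;
    scale-consistent in beds (HRDI(c*beds) = c*HRDI(beds)).
    """
    beds = np.asarray(beds, dtype=float)
    population = np.asarray(population, dtype=float)
    land_area = np.asarray(land_area, dtype=float)
    if np.any(population <= 0):
        raise PanelValidationError("population must be > 0 for HRDI")
    if np.any(land_area <= 0):
        raise PanelValidationError("land_area must be > 0 for HRDI")
    if np.any(beds < 0):
        raise PanelValidationError("beds must be >= 0 for HRDI")
    return np.sqrt((beds / (population / 1000.0)) * (beds / land_area))


def beds_from_hrdi(hrdi, population, land_area):
    """Invert compute_hrdi: the bed count whose HRDI equals the given value."""
    return np.asarray(hrdi, dtype=float) * np.sqrt(
        np.asarray(population, dtype=float) * np.asarray(land_area, dtype=float) / 1000.0
    )


# ---------------------------------------------------------------------------
# VIF screening


def _vif_values(x: np.ndarray) -> np.ndarray:
    """VIF_k = 1/(1-R^2_k) from regressing column k on the others (+ intercept)."""
    n, k = x.shape
    vifs = np.empty(k)
    ones = np.ones((n, 1))
    for j in range(k):
        yj = x[:, j]
        others = np.hstack([ones, np.delete(x, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        yc = yj - yj.mean()
        ss_tot = float(yc @ yc)
        r2 = 1.0 - ss_res / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_screen(
    table, threshold: float = 5.0, standardize: bool = False
) -> tuple[list[str], dict[str, float], list[str]]:
    """Iterative VIF-based multicollinearity screen.

    ``table``: DataFrame (columns = covariates) or 2-D array.  Repeatedly
    drops the covariate with the highest VIF while any VIF exceeds
    ``threshold`` (ties, including perfect collinearity, drop the
    later-listed column), then recomputes.

    Returns (retained names, final VIF per retained name, dropped names
    in drop order).
    """
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        names = [f"X{j+1}" for j in range(x.shape[1])]
    if x.shape[1] < 2:
        raise PanelValidationError("VIF screening needs at least 2 covariates")
    stds = x.std(axis=0)
    constant = [names[j] for j in np.nonzero(stds == 0)[0]]
    if constant:
        raise PanelValidationError(f"constant covariate column(s): {constant}")
    if standardize:
        x = (x - x.mean(axis=0)) / stds

    active = list(range(len(names)))
    dropped: list[str] = []
    while len(active) >= 2:
        vifs = _vif_values(x[:, active])
        vmax = vifs.max()
        if vmax <= threshold:
            break
        # later-listed column among ties is dropped
        worst_local = max(np.nonzero(vifs == vmax)[0])
        dropped.append(names[active[worst_local]])
        del active[worst_local]
    if len(active) >= 2:
        final = _vif_values(x[:, active])
    else:
        final = np.ones(len(active))
    retained = [names[j] for j in active]
    return retained, dict(zip(retained, final.tolist())), dropped
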