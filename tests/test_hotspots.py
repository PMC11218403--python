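import math

import numpy as np
import pytest

import geotriad as gt
from geotriad.hotspots import GiStarCube, summarize_pattern_counts


def gi_star_brute(values, neighbor_sets):
    """Literal loop transcription of the Gi* statistic with a
    self-inclusive binary star neighborhood and global mean/SD."""
    n = len(values)
    ybar = sum(values) / n
    s = math.sqrt(sum(v * v for v in values) / n - ybar**2)
    out = []
    for i in range(n):
        star = set(neighbor_sets[i]) | {i}
        wsum = sum(values[j] for j in star)
        sw = len(star)  # binary weights: sum w = sum w^2 = |star|
        out.append((wsum - ybar * sw) / (s * math.sqrt((n * sw - sw * sw) / (n - 1))))
    return np.array(out)


def gi_star_spacetime_brute(values, neighbor_sets):
    """Space-time Gi*: each (i, t) bin's neighborhood is the star set in
    years t-1, t, t+1; mean/SD over all N*T bins."""
    n, t = values.shape
    ntot = n * t
    ybar = values.mean()
    s = math.sqrt((values**2).mean() - ybar**2)
    z = np.empty((n, t))
    for i in range(n):
        star = set(neighbor_sets[i]) | {i}
        for tt in range(t):
            yrs = [u for u in (tt - 1, tt, tt + 1) if 0 <= u < t]
            wsum = sum(values[j, u] for j in star for u in yrs)
            sw = len(star) * len(yrs)
            z[i, tt] = (wsum - ybar * sw) / (
                s * math.sqrt((ntot * sw - sw * sw) / (ntot - 1))
            )
    return z


def plateau_field(rng=None):
    """5x5 rook lattice with a seeded high plateau in one corner."""
    w = gt.make_lattice_weights(5, 5, "rook")
    values = np.ones(25)
    if rng is not None:
        values += 0.1 * rng.standard_normal(25)
    for cell in (0, 1, 5, 6):
        values[cell] += 5.0
    return values, w


class TestGiStarSlice:
    def test_constant_field_zero_with_warning(self):
        w = gt.make_lattice_weights(3, 3, "rook")
        with pytest.warns(UserWarning, match="degenerate"):
            z = gt.gi_star_slice(np.full(9, 2.0), w)
        np.testing.assert_array_equal(z, 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        w = gt.make_lattice_weights(5, 5, "queen")
        y = rng.uniform(0, 10, 25)
        z = gt.gi_star_slice(y, w)
        np.testing.assert_allclose(gt.gi_star_slice(3.0 + 2.5 * y, w), z, atol=1e-10)

    def test_matches_brute_force_on_plateau(self):
        values, w = plateau_field(np.random.default_rng(2))
        z = gt.gi_star_slice(values, w)
        np.testing.assert_allclose(z, gi_star_brute(values, w.neighbor_sets), atol=1e-10)

    def test_permutation_distribution_sanity(self):
        # permuting an irregular field: z_i should be approximately
        # standard normal across permutations
        rng = np.random.default_rng(8)
        w = gt.make_lattice_weights(6, 5, "rook")
        y = rng.lognormal(0, 0.7, 30)
        i = 12
        zs = np.empty(2000)
        for m in range(2000):
            zs[m] = gt.gi_star_slice(rng.permutation(y), w)[i]
        assert abs(zs.mean()) < 0.05
        assert 0.9 < zs.std() < 1.1


class TestGiStarCube:
    def test_identical_years_identical_columns(self):
        values, w = plateau_field(np.random.default_rng(3))
        cube = gt.gi_star_cube(np.tile(values[:, None], (1, 5)), w)
        for t in range(1, 5):
            np.testing.assert_array_equal(cube.z[:, t], cube.z[:, 0])

    def test_window0_columns_equal_slices(self, small_panel):
        panel, weights, _ = small_panel
        cube = gt.gi_star_cube(panel, weights, temporal_window=0)
        for t in range(panel.n_years):
            np.testing.assert_allclose(
                cube.z[:, t], gt.gi_star_slice(panel.response[:, t], weights), atol=1e-12
            )

    def test_window1_matches_spacetime_brute_force(self):
        rng = np.random.default_rng(4)
        values, w = plateau_field(rng)
        cube_vals = np.column_stack([values + 0.05 * rng.standard_normal(25) for _ in range(4)])
        cube = gt.gi_star_cube(cube_vals, w, temporal_window=1)
        np.testing.assert_allclose(
            cube.z, gi_star_spacetime_brute(cube_vals, w.neighbor_sets), atol=1e-10
        )

    def test_significance_bins_follow_z(self, small_panel):
        panel, weights, _ = small_panel
        cube = gt.gi_star_cube(panel, weights)
        ns = cube.significance == "ns"
        np.testing.assert_array_equal(ns, np.abs(cube.z) < 1.645)
        assert np.all((cube.z >= 2.576) == (cube.significance == "hot99"))


class TestMannKendall:
    def test_strictly_increasing_maximal_s(self):
        s, _, z, p = gt.mann_kendall([1, 2, 3, 4, 5])
        assert s == 10 and p < 0.05 and z > 0

    def test_constant_series(self):
        s, var_s, z, p = gt.mann_kendall([2.0] * 6)
        assert s == 0 and z == 0.0 and p == 1.0

    def test_example_pair_enumeration(self):
        s, _, _, _ = gt.mann_kendall([3, 1, 2, 4])
        assert s == 2

    def test_random_series_match_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            x = np.round(rng.normal(size=n), 1)  # rounding creates ties
            s, var_s, z, p = gt.mann_kendall(x)
            s_brute = sum(
                np.sign(x[v] - x[u]) for u in range(n) for v in range(u + 1, n)
            )
            assert s == s_brute


def cube_from_z(z_rows: dict[str, list[float]]) -> tuple[GiStarCube, list[str]]:
    z = np.array(list(z_rows.values()), dtype=float)
    p = np.ones_like(z)
    return GiStarCube(z=z, p=p, significance=np.empty(z.shape, dtype=object)), list(z_rows)


class TestClassifier:
    def test_rule_examples(self):
        hot = 2.5
        scenarios = {
            "always_hot_rising": list(np.linspace(2.0, 5.1, 10)),  # intensifying
            "only_final_hot": [0.0] * 9 + [hot],  # new
            "never_significant": [0.5, -0.3, 1.0, 0.2, -0.9, 0.1, 0.4, -0.2, 0.8, 0.0],
            "short_run_to_end": [0.0] * 6 + [hot] * 4,  # consecutive
            "steady_high_no_trend": [2.5, 2.6, 2.4, 2.5, 2.6, 2.4, 2.5, 2.6, 2.4, 2.5],
            "gappy_hot_end_hot": [hot, 0.0, hot, 0.0, 0.0, hot, 0.0, hot, 0.0, hot],
            "cold_then_hot": [-2.5, -2.5, 0.0, hot, 0.0, 0.0, 0.0, 0.0, 0.0, hot],
            # rising hot history, final step cooled below threshold
            "hot_history_cool_end": list(np.linspace(2.0, 5.0, 9)) + [0.0],
            "always_hot_falling": list(np.linspace(5.1, 2.0, 10)),  # diminishing
            "cold_run_to_end": [0.0] * 6 + [-hot] * 4,  # consecutive cold
        }
        cube, ids = cube_from_z(scenarios)
        cats = {r.area_id: r.category for r in gt.classify_emerging_pattern(cube, ids)}
        assert cats["always_hot_rising"] == "intensifying hot spot"
        assert cats["only_final_hot"] == "new hot spot"
        assert cats["never_significant"] == "no pattern"
        assert cats["short_run_to_end"] == "consecutive hot spot"
        assert cats["steady_high_no_trend"] == "persistent hot spot"
        assert cats["gappy_hot_end_hot"] == "sporadic hot spot"
        assert cats["cold_then_hot"] == "oscillating hot spot"
        assert cats["hot_history_cool_end"] == "historical hot spot"
        assert cats["always_hot_falling"] == "diminishing hot spot"
        assert cats["cold_run_to_end"] == "consecutive cold spot"

    def test_classifier_total_and_permutation_equivariant(self, small_panel):
        panel, weights, _ = small_panel
        cube = gt.gi_star_cube(panel, weights)
        res = gt.classify_emerging_pattern(cube, panel.area_ids)
        assert len(res) == panel.n_areas  # total: every area classified
        perm = np.random.default_rng(6).permutation(panel.n_areas)
        cube_p = GiStarCube(z=cube.z[perm], p=cube.p[perm], significance=cube.significance[perm])
        res_p = gt.classify_emerging_pattern(cube_p, [panel.area_ids[i] for i in perm])
        by_id = {r.area_id: r.category for r in res}
        assert all(r.category == by_id[r.area_id] for r in res_p)

    def test_fdr_flag_is_no_less_conservative(self, small_panel):
        # Benjamini-Hochberg within each year can only shrink the set of
        # per-year significant steps, so patterned areas cannot increase
        panel, weights, _ = small_panel
        cube = gt.gi_star_cube(panel, weights)
        plain = gt.summarize_patterns(gt.classify_emerging_pattern(cube, panel.area_ids))
        fdr = gt.summarize_patterns(
            gt.classify_emerging_pattern(cube, panel.area_ids, fdr=True)
        )
        assert fdr["n_patterned"] <= plain["n_patterned"]

    def test_golden_preset(self):
        panel, weights, designed = gt.hotspot_preset(seed=0)
        cube = gt.gi_star_cube(panel, weights)
        cats = np.array([r.category for r in gt.classify_emerging_pattern(cube, panel.area_ids)])
        for want, idxs in designed.items():
            assert (cats[idxs] == want).all(), f"{want}: got {set(cats[idxs])}"


class TestSummaries:
    def test_counts_to_percentages(self):
        counts = {
            "consecutive hot spot": 257,
            "diminishing hot spot": 2,
            "intensifying hot spot": 65,
            "new hot spot": 50,
            "persistent hot spot": 20,
            "sporadic hot spot": 58,
            "consecutive cold spot": 120,
        }
        out = summarize_pattern_counts(counts, 2308)
        assert out["pct_patterned"] == 24.78
        assert out["pct_hot_of_patterned"] == 79.02
        assert out["pct_cold_of_patterned"] == 20.98
        assert out["categories"]["consecutive hot spot"]["pct_of_patterned"] == 44.93

    def test_empty_summary(self):
        out = summarize_pattern_counts({}, 100)
        assert out["n_patterned"] == 0 and out["pct_patterned"] == 0.0

    def test_summarize_from_results(self, small_panel):
        panel, weights, _ = small_panel
        cube = gt.gi_star_cube(panel, weights)
        res = gt.classify_emerging_pattern(cube, panel.area_ids)
        out = gt.summarize_patterns(res)
        # percentages recompute from counts
        if out["n_patterned"]:
            for cat, row in out["categories"].items():
                assert row["pct_of_patterned"] == pytest.approx(
                    100 * row["count"] / out["n_patterned"], abs=0.005
                )
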