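import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmrst import (
    SpaceTimeCube,
    classify_ehsa,
    emerging_hotspot_analysis,
    getis_ord_gistar_st,
    mann_kendall,
    sdg_classification,
    summarize_categories,
)
from mmrst.core import LatticeGeometry, SpaceTimePanel
from mmrst.ehsa import EHSA_CATEGORIES, percentage
from mmrst.weights import (
    SpatialWeights,
    rook_adjacency,
    space_time_neighbors,
)


def grid_world(rows, cols):
    geom = LatticeGeometry(
        {f"g{r}_{c}": (r, c) for r in range(rows) for c in range(cols)}
    )
    return geom, rook_adjacency(geom)


def gistar_oracle(cube, nbhd):
    """Naive triple-loop evaluation of the space-time Gi* definition."""
    X = cube.values
    K, T = X.shape
    n = K * T
    xbar = X.mean()
    s = np.sqrt((X**2).sum() / n - xbar**2)
    z = np.zeros_like(X)
    for i in range(K):
        for t in range(T):
            nb = nbhd.neighbors(i, t)
            tot = sum(X[j, tt] for j, tt in nb)
            m = len(nb)
            z[i, t] = (tot - xbar * m) / (s * np.sqrt((n * m - m * m) / (n - 1)))
    return z


class TestGiStar:
    def test_constant_cube_degenerate(self):
        _, w = grid_world(2, 2)
        cube = SpaceTimeCube(w.ids, (0, 1, 2), np.full((4, 3), 5.0))
        gi = getis_ord_gistar_st(cube, space_time_neighbors(w, 3, 1))
        assert gi.degenerate
        assert np.all(gi.z == 0.0)

    def test_single_unit_hand_eval(self):
        w = SpatialWeights(["a"], {0: []})
        x = np.array([[1.0, 2.0, 3.0, 4.0, 10.0]])
        cube = SpaceTimeCube(("a",), (0, 1, 2, 3, 4), x)
        nbhd = space_time_neighbors(w, 5, 1)
        gi = getis_ord_gistar_st(cube, nbhd)
        n = 5
        xbar = x.mean()
        s = np.sqrt((x**2).mean() - xbar**2)
        # interior bin t=2: sum over {1,2,3} = 9, |N| = 3
        expect = (9 - xbar * 3) / (s * np.sqrt((n * 3 - 9) / (n - 1)))
        assert gi.z[0, 2] == pytest.approx(expect, abs=1e-12)

    def test_spike_ordering(self):
        # every bin whose neighborhood contains the spike scores strictly
        # positive and above every bin that does not (the spike's excess is
        # identical across containing bins, so ties across them are fine)
        _, w = grid_world(3, 3)
        vals = np.ones((9, 4))
        vals[4, 2] = 30.0  # center unit, one bin far above the rest
        cube = SpaceTimeCube(w.ids, (0, 1, 2, 3), vals)
        nbhd = space_time_neighbors(w, 4, 1)
        gi = getis_ord_gistar_st(cube, nbhd)
        containing = np.zeros((9, 4), dtype=bool)
        for i in range(9):
            for t in range(4):
                containing[i, t] = (4, 2) in nbhd.neighbors(i, t)
        assert gi.z[4, 2] > 0
        assert containing[4, 2]
        assert gi.z[containing].min() > 0
        assert gi.z[containing].min() > gi.z[~containing].max()

    @pytest.mark.parametrize("lag", [0, 1, 2])
    def test_matches_triple_loop_oracle(self, lag):
        rng = np.random.default_rng(lag)
        _, w = grid_world(3, 2)
        T = 6
        cube = SpaceTimeCube(
            w.ids, tuple(range(T)), rng.random((w.n, T)) * 10
        )
        nbhd = space_time_neighbors(w, T, lag)
        gi = getis_ord_gistar_st(cube, nbhd)
        np.testing.assert_allclose(gi.z, gistar_oracle(cube, nbhd), atol=1e-10)


class TestMannKendall:
    def test_increasing(self):
        s, var_s, z, p = mann_kendall([1, 2, 3, 4])
        assert s == 6
        assert var_s == pytest.approx(26 / 3)
        assert z == pytest.approx(5 / np.sqrt(26 / 3))

    def test_reversal_negates_s(self):
        rng = np.random.default_rng(0)
        x = rng.random(10)
        s1, *_ = mann_kendall(x)
        s2, *_ = mann_kendall(x[::-1])
        assert s1 == -s2

    def test_all_tied(self):
        s, var_s, z, p = mann_kendall([1.0, 1.0, 1.0])
        assert (s, var_s, z, p) == (0, 0.0, 0.0, 1.0)

    def test_exhaustive_pair_enumeration(self):
        # every series of length <= 5 over {0,1,2}; lengths up to 8 are
        # covered by the acceptance suite
        for n in range(2, 6):
            for combo in itertools.product((0.0, 1.0, 2.0), repeat=n):
                s, *_ = mann_kendall(combo)
                brute = sum(
                    np.sign(combo[l] - combo[k])
                    for k in range(n)
                    for l in range(k + 1, n)
                )
                assert s == brute


class TestClassifier:
    H = 3.0  # comfortably past the 1.96 cut

    def test_persistent(self):
        assert classify_ehsa([self.H] * 6) == "persistent hot spot"

    def test_new(self):
        assert classify_ehsa([0, 0, 0, 0, self.H]) == "new hot spot"

    def test_oscillating(self):
        z = [self.H, -self.H, self.H, -self.H, self.H]
        assert classify_ehsa(z) == "oscillating hot spot"

    def test_consecutive(self):
        z = [0, 0, 0, self.H, self.H]
        assert classify_ehsa(z) == "consecutive hot spot"

    def test_sporadic(self):
        z = [self.H, 0, self.H, 0, self.H]
        assert classify_ehsa(z) == "sporadic hot spot"

    def test_historical(self):
        z = [self.H] * 9 + [0.0]
        assert classify_ehsa(z) == "historical hot spot"

    def test_intensifying_and_diminishing(self):
        up = np.linspace(2.0, 6.0, 12)
        down = up[::-1]
        assert classify_ehsa(up) == "intensifying hot spot"
        assert classify_ehsa(down) == "diminishing hot spot"

    def test_no_pattern(self):
        assert classify_ehsa([0.1, -0.2, 0.3, 0.0]) == "no pattern detected"

    def test_total_function(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            z = rng.normal(0, 2.5, size=int(rng.integers(2, 15)))
            assert classify_ehsa(z) in EHSA_CATEGORIES

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(2)
        swap = {"hot": "cold", "cold": "hot"}
        for _ in range(400):
            z = rng.normal(0, 2.5, size=int(rng.integers(2, 15)))
            cat = classify_ehsa(z)
            neg = classify_ehsa(-z)
            if cat == "no pattern detected":
                assert neg == cat
            else:
                kind, side, _ = cat.split()
                assert neg == f"{kind} {swap[side]} spot"


class TestEmergingHotspot:
    def test_planted_block_is_hot(self):
        rng = np.random.default_rng(3)
        _, w = grid_world(6, 6)
        T = 10
        vals = rng.normal(10.0, 0.5, (36, T))
        hot_units = [i for i, u in enumerate(w.ids) if u in
                     ("g0_0", "g0_1", "g1_0", "g1_1")]
        vals[hot_units] += 25.0
        panel = SpaceTimePanel(w.ids, tuple(range(2000, 2000 + T)), vals)
        res = emerging_hotspot_analysis(panel, w, lag=1)
        cats = res.table.set_index("unit_id")["category"]
        for i in hot_units:
            assert cats[w.ids[i]].endswith("hot spot")
        assert cats["g5_5"] in ("no pattern detected",) or cats[
            "g5_5"
        ].endswith("cold spot")

    def test_summary_percentages_sum(self, small_panel, small_world):
        _, _, w = small_world
        panel, _ = small_panel
        res = emerging_hotspot_analysis(panel, w)
        assert res.summary["count"].sum() == panel.n_units
        assert abs(res.summary["percentage"].sum() - 100.0) < 0.05

    def test_determinism(self, small_panel, small_world):
        _, _, w = small_world
        panel, _ = small_panel
        a = emerging_hotspot_analysis(panel, w)
        b = emerging_hotspot_analysis(panel, w)
        assert list(a.table["category"]) == list(b.table["category"])
        np.testing.assert_array_equal(a.gistar.z, b.gistar.z)


class TestBookkeeping:
    @pytest.mark.parametrize(
        "count,total,expect",
        [(1598, 2894, 55.22), (0, 2894, 0.00), (2294, 2894, 79.27)],
    )
    def test_summarize(self, count, total, expect):
        table = summarize_categories({"x": count}, total)
        assert table["percentage"].iloc[0] == expect

    def test_rounding_half_up(self):
        assert percentage(1, 8) == 12.5
        assert percentage(1, 800) == 0.13  # 0.125 rounds up, not to even

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            summarize_categories({"x": 10}, 5)
        with pytest.raises(ValueError):
            summarize_categories({"x": 1}, 0)

    def test_sdg_strict_boundary(self):
        panel = SpaceTimePanel(
            ("a", "b"), (2015,), np.array([[69.9], [70.0]])
        )
        flags, yearly = sdg_classification(panel, threshold=70)
        by_unit = flags.set_index("county_id")["achieved"]
        assert bool(by_unit["a"]) is True
        assert bool(by_unit["b"]) is False
        assert yearly["achieved_count"].iloc[0] == 1

    def test_sdg_paper_counts(self):
        assert percentage(2703, 2894) == 93.40
        assert percentage(191, 2894, decimals=1) == 6.6

    def test_incomplete_panel_explicit_error(self):
        df = pd.DataFrame(
            {
                "county_id": ["a", "b", "a"],
                "year": [2000, 2000, 2001],
                "value": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match=r"\('b', 2001\)"):
            SpaceTimePanel.from_long_frame(df)
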