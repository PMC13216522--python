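"""Space-time cube, bin Gi*, FDR, Mann-Kendall, 17-category rule table."""

import itertools

import numpy as np
import pandas as pd
import pytest

from screenscape.emerging import (CATEGORIES, bin_gi_star, build_cube,
                                  classify_location, ehsa, fdr_adjust,
                                  mann_kendall)


# ------------------------------------------------------------------ oracle

def classify_oracle(s: str, trend: str) -> str:
    """Independent rule-table implementation on an indicator string.

    ``s`` holds one character per period: H (hot bin), C (cold bin),
    N (neither).  Hot categories take precedence over cold; within a family
    the precedence is new, consecutive, intensifying/persistent/diminishing,
    sporadic, oscillating, historical.
    """
    if len(s) < 2:
        return "no_pattern"

    def family(x, opp, tr):
        frac = s.count(x) / len(s)
        final = s.endswith(x)
        run = len(s) - len(s.rstrip(x))
        if final and x not in s[:-1]:
            return "new"
        if final and run >= 2 and x not in s[:-run] and frac < 0.9:
            return "consecutive"
        if frac >= 0.9:
            return {"up": "intensifying", "down": "diminishing"}.get(tr, "persistent")
        if final and opp not in s:
            return "sporadic"
        if final and opp in s[:-1]:
            return "oscillating"
        if not final and frac >= 0.5:
            return "historical"
        return None

    hot = family("H", "C", {"increasing": "up", "decreasing": "down"}.get(trend))
    if hot:
        return hot + "_hot"
    cold = family("C", "H", {"increasing": "down", "decreasing": "up"}.get(trend))
    if cold:
        return cold + "_cold"
    return "no_pattern"


def _series(s: str):
    hot = np.array([c == "H" for c in s])
    cold = np.array([c == "C" for c in s])
    return hot, cold


# ------------------------------------------------------------------- tests

class TestCube:
    def make_panel(self, L, T, value=50.0):
        return pd.DataFrame({
            "neighborhood_id": np.repeat(np.arange(L), T),
            "period": np.tile(2004 + 2 * np.arange(T), L),
            "sebs_rate": value})

    def test_capacity(self):
        cube = build_cube(self.make_panel(2121, 9))
        assert cube.capacity == 19089

    def test_missing_cells_masked_not_imputed(self):
        panel = self.make_panel(5, 4)
        panel = panel[~((panel.neighborhood_id == 2)
                        & panel.period.isin([2006, 2008]))]
        cube = build_cube(panel)
        assert cube.mask.sum() == 18
        assert (~cube.mask[2]).sum() == 2
        assert np.isnan(cube.values[2, 1])

    def test_row_order_invariance(self):
        panel = self.make_panel(6, 3)
        panel["sebs_rate"] = np.arange(len(panel), dtype=float)
        a = build_cube(panel)
        b = build_cube(panel.sample(frac=1, random_state=0))
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_period_rejected(self):
        with pytest.raises(ValueError, match="2 periods"):
            build_cube(self.make_panel(5, 1))


class TestBinGiStar:
    @staticmethod
    def centroids(L, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        return pd.DataFrame({"neighborhood_id": np.arange(L),
                             "x": rng.random(L), "y": rng.random(L)})

    def test_constant_cube_flags_nothing(self):
        panel = TestCube().make_panel(30, 4)
        cube = build_cube(panel)
        bins = fdr_adjust(bin_gi_star(cube, self.centroids(30), spatial_k=4))
        assert (bins["indicator"] == "neither").all()

    def test_elevated_block_positive_z(self):
        panel = TestCube().make_panel(30, 5)
        block = panel.neighborhood_id.isin([0, 1, 2]) & panel.period.isin(
            [2006, 2008, 2010])
        panel.loc[block, "sebs_rate"] = 90.0
        cube = build_cube(panel)
        cent = pd.DataFrame({"neighborhood_id": np.arange(30),
                             "x": np.arange(30) * 1.0, "y": 0.0})
        bins = bin_gi_star(cube, cent, spatial_k=2)
        sub = bins[bins.neighborhood_id.isin([0, 1, 2])
                   & bins.period.isin([2006, 2008, 2010])]
        assert (sub["z"] > 0).all()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        L, T, k, tw = 20, 5, 4, 1
        panel = TestCube().make_panel(L, T)
        panel["sebs_rate"] = rng.random(len(panel)) * 100
        # knock out a few bins to exercise the renormalization
        panel = panel.drop(panel.index[[3, 17, 44]])
        cent = self.centroids(L, rng_seed=4)
        cube = build_cube(panel)
        bins = bin_gi_star(cube, cent, spatial_k=k, temporal_window=tw)

        from screenscape.hotspots import build_knn
        w = build_knn(cent[["x", "y"]].to_numpy(), k=k)
        obs = cube.values[cube.mask]
        n, xbar, s = obs.size, obs.mean(), obs.std()
        for _, row in bins.iterrows():
            i = int(row.neighborhood_id)
            t = list(cube.periods).index(row.period)
            if not cube.mask[i, t]:
                assert np.isnan(row.z)
                continue
            total, wi = 0.0, 0
            for j in [i, *w.neighbors[i]]:
                for tt in range(max(0, t - tw), min(T, t + tw + 1)):
                    if cube.mask[j, tt]:
                        total += cube.values[j, tt]
                        wi += 1
            expected = (total - xbar * wi) / (
                s * np.sqrt((n * wi - wi**2) / (n - 1)))
            assert row.z == pytest.approx(expected, abs=1e-10)


class TestFDR:
    def bins(self, pvals, z=None):
        z = np.ones(len(pvals)) if z is None else np.asarray(z, float)
        return pd.DataFrame({"neighborhood_id": np.arange(len(pvals)),
                             "period": 2004, "z": z, "p": pvals})

    def test_all_ones_no_rejections(self):
        out = fdr_adjust(self.bins([1.0, 1.0, 1.0]))
        assert (out["indicator"] == "neither").all()

    def test_step_up_example(self):
        # BH on (0.001, 0.02, 0.9) at alpha 0.05: thresholds 0.0167/0.033/0.05
        out = fdr_adjust(self.bins([0.001, 0.02, 0.9], z=[2, -2, 1]))
        assert list(out["indicator"]) == ["hot", "cold", "neither"]

    def test_duplication_preserves_decisions(self):
        p = [0.003, 0.04, 0.2, 0.8]
        single = fdr_adjust(self.bins(p))["indicator"]
        double = fdr_adjust(self.bins(p + p))["indicator"]
        assert list(double[:4]) == list(single) == list(double[4:])

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(0)
        p = rng.random(200) ** 2
        strict = fdr_adjust(self.bins(p), alpha=0.01)["indicator"] != "neither"
        loose = fdr_adjust(self.bins(p), alpha=0.05)["indicator"] != "neither"
        assert (loose | ~strict).all()


def mk_oracle(x):
    """Pair enumeration plus the tie-corrected variance formula."""
    x = np.asarray(x, float)
    n = len(x)
    s = sum(np.sign(x[j] - x[i]) for i in range(n) for j in range(i + 1, n))
    ties = [np.sum(x == v) for v in np.unique(x)]
    var = (n * (n - 1) * (2 * n + 5)
           - sum(t * (t - 1) * (2 * t + 5) for t in ties)) / 18
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return int(s), z


class TestMannKendall:
    def test_strictly_increasing_length_9(self):
        mk = mann_kendall(np.arange(9.0))
        assert mk["S"] == 36
        assert mk["z"] == pytest.approx(35 / np.sqrt(92))
        assert mk["direction"] == "increasing"

    def test_antisymmetry(self):
        x = np.array([1.0, 5, 2, 8, 3, 9, 4])
        a, b = mann_kendall(x), mann_kendall(x[::-1])
        assert a["S"] == -b["S"]
        assert a["z"] == pytest.approx(-b["z"])

    def test_constant_series_no_trend(self):
        mk = mann_kendall(np.full(6, 3.0))
        assert mk["S"] == 0 and mk["direction"] == "none"

    def test_short_series_flagged_none(self):
        assert mann_kendall([1.0, 2.0, 3.0])["direction"] == "none"

    def test_all_permutations_up_to_length_6_match_oracle(self):
        for n in (4, 5, 6):
            for perm in itertools.permutations(range(n)):
                mk = mann_kendall(np.array(perm, dtype=float))
                s, z = mk_oracle(perm)
                assert mk["S"] == s
                assert mk["z"] == pytest.approx(z, abs=1e-12)

    def test_tied_values_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 4, size=8).astype(float)
            if np.unique(x).size == 1:
                continue
            mk = mann_kendall(x)
            s, z = mk_oracle(x)
            assert mk["S"] == s and mk["z"] == pytest.approx(z, abs=1e-12)


class TestClassifier:
    @pytest.mark.parametrize("s,trend,expected", [
        ("HHHHHHHHH", "increasing", "intensifying_hot"),
        ("HHHHHHHHH", "none", "persistent_hot"),
        ("HHHHHHHHH", "decreasing", "diminishing_hot"),
        ("NNNNNNNNH", "none", "new_hot"),
        ("NNNNNNNHH", "none", "consecutive_hot"),
        ("HNHNHNHNH", "none", "sporadic_hot"),
        ("CNHNHNHNH", "none", "oscillating_hot"),
        ("HHHHHNNNN", "none", "historical_hot"),   # 5 of 9 under the 50% rule
        ("CCCCCCCCC", "decreasing", "intensifying_cold"),
        ("NNNNNNNNC", "none", "new_cold"),
        ("NNNNNNNNN", "increasing", "no_pattern"),
    ])
    def test_named_examples(self, s, trend, expected):
        hot, cold = _series(s)
        assert classify_location(hot, cold, trend) == expected

    def test_vocabulary_is_17_labels(self):
        assert len(CATEGORIES) == 17
        assert len(set(CATEGORIES)) == 17

    def test_exhaustive_length_5_matches_oracle(self):
        for chars in itertools.product("HCN", repeat=5):
            s = "".join(chars)
            hot, cold = _series(s)
            for trend in ("increasing", "decreasing", "none"):
                got = classify_location(hot, cold, trend)
                assert got == classify_oracle(s, trend), (s, trend)
                assert got in CATEGORIES

    def test_overlapping_indicators_assert(self):
        with pytest.raises(AssertionError):
            classify_location([True, True], [True, False], "none")


def test_ehsa_end_to_end_recovers_planted_core(small_panel, small_centroids,
                                               small_canton):
    res = ehsa(small_panel, small_centroids)
    locs = res["locations"].set_index("neighborhood_id")
    truth = small_canton.truth.set_index("neighborhood_id")["trajectory"]
    hot_ids = truth[truth == "persistent_hot"].index
    assert locs.loc[hot_ids, "category"].str.endswith("_hot").mean() >= 0.75
    assert set(locs["category"]) <= set(CATEGORIES)
    # deterministic
    res2 = ehsa(small_panel, small_centroids)
    pd.testing.assert_frame_equal(res["locations"], res2["locations"])
    # the category-period surface covers every emitted category
    assert (set(res["category_period_means"]["category"])
            == set(locs["category"].unique()))
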