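"""Diversity statistics: closed-form checks for Shannon and Bray-Curtis,
PCoA round-trips, PERMANOVA against a direct sum-of-squares decomposition
and an external reference implementation, rank tests and the per-animal
longitudinal analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viropipe import diversity
from viropipe.diversity import (
    bray_curtis,
    group_compare,
    longitudinal_dissimilarity,
    pcoa,
    permanova,
    shannon,
)


class TestShannon:
    def test_uniform_four_groups(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_group_zero(self):
        assert shannon([0, 17, 0]) == 0.0

    def test_hand_closed_form(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        assert shannon([2, 1, 1]) == pytest.approx(1.0397207708399179)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([3, 2, 1], [3, 2, 1]) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([5, 0, 0], [0, 2, 3]) == 1.0

    def test_hand_value(self):
        # 1 - 2*1/5
        assert bray_curtis([2, 0, 1], [1, 1, 0]) == pytest.approx(0.6)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=8),
        st.lists(st.integers(0, 100), min_size=2, max_size=8),
    )
    def test_symmetric_and_bounded(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))


class TestPcoa:
    def test_three_equidistant_points(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        res = pcoa(d)
        assert res.variance_explained[:2] == pytest.approx([50.0, 50.0])

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d))
        coords = res.coordinates.values[:, :2]
        d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.abs(d2 - d).max() < 1e-8

    def test_duplicate_sample_identical_coordinates(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3))
        pts = np.vstack([pts, pts[0]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d))
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[-1], atol=1e-8)

    def test_axis_variances_non_increasing_and_bounded(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d))
        assert (np.diff(res.variance_explained) <= 1e-9).all()
        assert res.variance_explained.sum() <= 100.0 + 1e-9

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(pd.DataFrame([[0.0, 1.0], [0.5, 0.0]]))


def _direct_ss_r2(d: np.ndarray, labels: np.ndarray) -> float:
    """Independent R^2: explicit SS_total / SS_within decomposition."""
    n = len(labels)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(
            d[i, j] ** 2 for k, i in enumerate(idx) for j in idx[k + 1:]
        ) / len(idx)
    return (ss_t - ss_w) / ss_t


class TestPermanova:
    def _toy(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(3, 1, (3, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        return pd.DataFrame(d), labels

    def test_r2_matches_direct_decomposition(self):
        d, labels = self._toy()
        res = permanova(d, labels, n_perm=19, seed=0)
        assert res["r2"] == pytest.approx(_direct_ss_r2(d.values, labels))

    def test_matches_reference_implementation(self):
        """Pseudo-F agrees with scikit-bio's PERMANOVA on the same matrix."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 3))
        pts[6:] += 1.5
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(pd.DataFrame(d), np.array(labels), n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d, ids=[str(i) for i in range(12)])
        ref = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert ours["pseudo_f"] == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_separated_clusters_significant(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 0.5, (6, 3)), rng.normal(5, 0.5, (6, 3))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = permanova(pd.DataFrame(d), np.array(["a"] * 6 + ["b"] * 6),
                        n_perm=999, seed=1)
        assert res["r2"] >= 0.5 and res["p_value"] <= 0.005

    def test_null_r2_mean_near_expectation(self):
        """For exchangeable data, E[R^2] ~ (g-1)/(n-1) under label shuffling."""
        rng = np.random.default_rng(6)
        r2s = []
        for _ in range(60):
            pts = rng.normal(size=(10, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            r2s.append(permanova(pd.DataFrame(d), labels, n_perm=0, seed=0)["r2"])
        assert np.mean(r2s) == pytest.approx(1 / 9, abs=0.05)

    def test_single_group_rejected(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            permanova(d, np.array(["a"] * 4))

    def test_deterministic_given_seed(self):
        d, labels = self._toy()
        a = permanova(d, labels, n_perm=99, seed=7)
        b = permanova(d, labels, n_perm=99, seed=7)
        assert a == b


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        grp = ["a"] * 4 + ["b"] * 4
        res = group_compare(vals, grp, test="wilcoxon", n_comparisons=3)
        assert res["p_adjusted"] == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)])
        grp = ["a"] * 10 + ["b"] * 10
        res = group_compare(vals, grp, n_comparisons=3)
        assert res["p_adjusted"] == min(1.0, res["p_value"] * 3)

    def test_kruskal_multi_group(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(m, 1, 8) for m in (0, 0, 5)])
        grp = np.repeat(["a", "b", "c"], 8)
        res = group_compare(vals, grp, test="kruskal")
        assert res["p_value"] < 0.01

    def test_power_for_large_shift(self):
        """A 3-SD shift with n=10 per group is detected (p < 0.01) in at
        least 95% of simulations."""
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 10)
            b = rng.normal(3, 1, 10)
            res = group_compare(np.concatenate([a, b]),
                                ["a"] * 10 + ["b"] * 10)
            hits += res["p_value"] < 0.01
        assert hits >= 95

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestLongitudinal:
    def _meta(self):
        rows = []
        for a, (trt, cage) in enumerate([("Sham", "C01"), ("Sham", "C01"),
                                         ("PFF", "C03")]):
            animal = f"{cage}-R{a + 1}"
            for tp in ("Base", "T1", "T5"):
                rows.append((f"{animal}-{tp}", animal, cage, trt, tp))
        return pd.DataFrame(
            rows, columns=["sample_id", "animal_id", "cage_id", "treatment", "timepoint"]
        )

    def test_identical_base_t1_zero_and_direction(self):
        meta = self._meta()
        profiles = {}
        rng = np.random.default_rng(10)
        base = rng.integers(1, 50, size=12).astype(float)
        shifted = base.copy()
        shifted[:4] *= 6
        for animal in meta["animal_id"].unique():
            profiles[f"{animal}-Base"] = base
            profiles[f"{animal}-T1"] = base  # identical at T1
            profiles[f"{animal}-T5"] = shifted
        table = pd.DataFrame(profiles)
        per_animal, by_trt, by_cage = longitudinal_dissimilarity(table, meta)
        assert (per_animal["bc_base_t1"] == 0).all()
        assert (per_animal["direction"] == "T5_more_dissimilar").all()
        assert set(by_trt.index) == {"Sham", "PFF"}
        assert set(by_cage.index) == {"C01", "C03"}

    def test_persistent_shift_pattern(self):
        """A shift at T1 that persists to T5 gives base-vs-T1 ~ base-vs-T5,
        both larger than T1-vs-T5."""
        meta = self._meta()
        rng = np.random.default_rng(11)
        table = {}
        for animal in meta["animal_id"].unique():
            base = rng.integers(10, 100, size=20).astype(float)
            shifted = base * rng.choice([0.2, 5.0], size=20)
            table[f"{animal}-Base"] = base
            table[f"{animal}-T1"] = shifted + rng.integers(0, 3, 20)
            table[f"{animal}-T5"] = shifted + rng.integers(0, 3, 20)
        per_animal, _, _ = longitudinal_dissimilarity(pd.DataFrame(table), meta)
        assert (per_animal["bc_base_t1"] > per_animal["bc_t1_t5"]).all()
        assert (per_animal["bc_base_t5"] > per_animal["bc_t1_t5"]).all()
        assert np.allclose(per_animal["bc_base_t1"], per_animal["bc_base_t5"], atol=0.1)

    def test_missing_base_skipped(self):
        meta = self._meta().query("sample_id != 'C01-R1-Base'")
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {s: rng.integers(1, 50, 10).astype(float) for s in meta["sample_id"]}
        )
        with pytest.warns(UserWarning):
            per_animal, _, _ = longitudinal_dissimilarity(table, meta)
        assert "C01-R1" not in set(per_animal["animal_id"])
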