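import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from thermogut import (DistanceMatrix, ModelFormula, adonis,
                       assemble_permanova_row, gower_center)

from conftest import make_metadata


def euclidean_dm(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    ids = ids or [f"s{i:02d}" for i in range(points.shape[0])]
    return DistanceMatrix(ids, squareform(pdist(points)))


def anova_ss_on_coordinates(y, design_blocks):
    """Independent oracle: sequential multivariate ANOVA sums of squares
    computed directly in coordinate space via cumulative projections."""
    y = y - y.mean(axis=0)
    n = y.shape[0]
    x = np.ones((n, 1))
    prev = x @ np.linalg.pinv(x)
    out = []
    for block in design_blocks:
        x = np.column_stack([x, block])
        h = x @ np.linalg.pinv(x)
        out.append(float(np.trace(y.T @ (h - prev) @ y)))
        prev = h
    resid = float(np.trace(y.T @ (np.eye(n) - prev) @ y))
    return out, resid


class TestGowerCenter:
    def test_trace_is_total_sum_of_squares(self):
        dm = euclidean_dm([0.0, 1.0, 10.0, 11.0])
        g = gower_center(dm)
        # sum of squared deviations of [0,1,10,11] from mean 5.5 = 101
        assert np.trace(g) == pytest.approx(101.0)

    def test_all_zero_distances(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        assert np.allclose(gower_center(dm), 0.0)

    def test_trace_invariant_under_reordering(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        dm = euclidean_dm(pts)
        perm = rng.permutation(6)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        assert np.trace(gower_center(dm)) == pytest.approx(
            np.trace(gower_center(dm2)))


class TestAdonis:
    def test_univariate_anova_identity(self):
        """1-D points [0,1,10,11], groups {0,1} vs {10,11}: hand ANOVA gives
        SS_between=100, SS_res=1, F=200."""
        dm = euclidean_dm([0.0, 1.0, 10.0, 11.0])
        meta = make_metadata(dm.ids, ["resistant"] * 2 + ["sensitive"] * 2,
                             ["warm24"] * 4)
        out = adonis(dm, meta, "tolerance", n_perm=0, seed=0)
        assert out.loc["tolerance", "SS"] == pytest.approx(100.0)
        assert out.loc["Residuals", "SS"] == pytest.approx(1.0)
        assert out.loc["tolerance", "pseudo_F"] == pytest.approx(200.0)
        assert out.loc["tolerance", "df"] == 1
        assert out.loc["Residuals", "df"] == 2

    def test_matches_vegan_adonis2(self):
        """Frozen oracle: vegan::adonis2(d ~ f1 + f2 + f1:f2, by="terms") on
        Euclidean distances of 12 standard-normal points in 4-D (seed 42)."""
        rng = np.random.default_rng(42)
        y = rng.normal(size=(12, 4))
        dm = euclidean_dm(y)
        meta = make_metadata(dm.ids,
                             ["resistant", "sensitive"] * 6,
                             ["warm24"] * 6 + ["cold12"] * 6)
        out = adonis(dm, meta, "tolerance + temperature + tolerance:temperature",
                     n_perm=0, seed=0)
        expected_ss = {"tolerance": 2.459956564, "temperature": 1.435154056,
                       "tolerance:temperature": 1.863781847,
                       "Residuals": 16.676355851, "Total": 22.435248318}
        for term, ss in expected_ss.items():
            assert out.loc[term, "SS"] == pytest.approx(ss, abs=1e-8)
        assert out.loc["tolerance", "pseudo_F"] == pytest.approx(1.18009, abs=1e-5)
        assert out.loc["tolerance", "R2"] == pytest.approx(0.1096469506, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_coordinate_space_anova(self, seed):
        """Random small multivariate instances: every sequential SS equals
        the brute-force coordinate-space ANOVA SS."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        y = rng.normal(size=(n, int(rng.integers(2, 5))))
        tol = rng.choice(["resistant", "sensitive"], size=n)
        temp = rng.choice(["warm24", "cold12"], size=n)
        if len(set(tol)) < 2 or len(set(temp)) < 2:
            pytest.skip("degenerate draw")
        dm = euclidean_dm(y)
        meta = make_metadata(dm.ids, list(tol), list(temp))
        out = adonis(dm, meta, "tolerance + temperature", n_perm=0, seed=0)
        blocks = [(tol == "sensitive").astype(float)[:, None],
                  ((temp == "warm24").astype(float))[:, None]]
        ss, resid = anova_ss_on_coordinates(y, blocks)
        assert out.loc["tolerance", "SS"] == pytest.approx(ss[0], abs=1e-8)
        assert out.loc["temperature", "SS"] == pytest.approx(ss[1], abs=1e-8)
        assert out.loc["Residuals", "SS"] == pytest.approx(resid, abs=1e-8)

    def test_matches_skbio_one_way(self):
        """Dual route: one-way pseudo-F agrees with scikit-bio's PERMANOVA."""
        import skbio
        rng = np.random.default_rng(7)
        y = rng.normal(size=(10, 3))
        y[:5] += 1.0
        dm = euclidean_dm(y)
        labels = ["resistant"] * 5 + ["sensitive"] * 5
        meta = make_metadata(dm.ids, labels, ["warm24"] * 10)
        ours = adonis(dm, meta, "tolerance", n_perm=0, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, ids=dm.ids), grouping=labels,
            permutations=0)
        assert ours.loc["tolerance", "pseudo_F"] == pytest.approx(
            theirs["test statistic"], rel=1e-9)

    def test_partition_identity_and_r2(self, default_study):
        _, table, meta, _, _ = default_study
        from thermogut import bray_curtis, filter_doubletons, rarefy
        rt = rarefy(filter_doubletons(table), 6000, seed=1)
        md = meta.select_samples(rt.sample_ids)
        dm = bray_curtis(rt)
        out = adonis(dm, md, "tolerance + temperature + family + part + "
                     "tolerance:temperature", n_perm=0, seed=0)
        g = gower_center(dm)
        terms = out.drop(index=["Residuals", "Total"])
        assert terms["SS"].sum() + out.loc["Residuals", "SS"] == pytest.approx(
            np.trace(g), rel=1e-8)
        assert terms["R2"].sum() + out.loc["Residuals", "R2"] == pytest.approx(1.0, rel=1e-10)
        assert terms["df"].sum() + out.loc["Residuals", "df"] == out.loc["Total", "df"]

    def test_sequential_ss_depends_on_order_partition_does_not(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(14, 3))
        tol = ["resistant"] * 7 + ["sensitive"] * 7
        temp = (["warm24"] * 4 + ["cold12"] * 3) * 2
        dm = euclidean_dm(y)
        meta = make_metadata(dm.ids, tol, temp)
        # unbalanced, correlated factors: order matters for the split
        a = adonis(dm, meta, "tolerance + temperature", n_perm=0, seed=0)
        b = adonis(dm, meta, "temperature + tolerance", n_perm=0, seed=0)
        assert a.loc["Total", "SS"] == pytest.approx(b.loc["Total", "SS"])
        assert a.loc["Residuals", "SS"] == pytest.approx(b.loc["Residuals", "SS"])

    def test_single_level_factor_rejected(self):
        dm = euclidean_dm([0.0, 1.0, 2.0])
        meta = make_metadata(dm.ids, ["resistant"] * 3, ["warm24"] * 3)
        with pytest.raises(ValueError, match="single level"):
            adonis(dm, meta, "tolerance", n_perm=0, seed=0)

    def test_numeric_factor_coding_gives_single_df(self, default_study):
        _, table, meta, _, _ = default_study
        from thermogut import bray_curtis
        sub_ids = table.sample_ids[::4]  # span all six families
        dm = bray_curtis(table.select_samples(sub_ids))
        md = meta.select_samples(sub_ids)
        natural = adonis(dm, md, "family", n_perm=0, seed=0)
        coded = adonis(dm, md, "family", n_perm=0, seed=0,
                       numeric_factors=("family",))
        assert natural.loc["family", "df"] > 1
        assert coded.loc["family", "df"] == 1

    def test_permutation_p_detects_signal(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(20, 3))
        y[:10] += 3.0
        dm = euclidean_dm(y)
        meta = make_metadata(dm.ids, ["resistant"] * 10 + ["sensitive"] * 10,
                             ["warm24"] * 20)
        out = adonis(dm, meta, "tolerance", n_perm=199, seed=5)
        assert out.loc["tolerance", "p"] == pytest.approx(1 / 200)

    def test_strata_restrict_permutations(self):
        """With strata equal to the tested factor, permutations cannot break
        the grouping, so p stays at 1."""
        rng = np.random.default_rng(12)
        y = rng.normal(size=(12, 2))
        y[:6] += 2.0
        dm = euclidean_dm(y)
        meta = make_metadata(dm.ids, ["resistant"] * 6 + ["sensitive"] * 6,
                             ["warm24"] * 12)
        out = adonis(dm, meta, "tolerance", n_perm=99, seed=1, strata="tolerance")
        assert out.loc["tolerance", "p"] == 1.0


class TestAssembleRow:
    def test_zero_ss_term(self):
        ms, f, r2 = assemble_permanova_row(0.0, 1, 10.0, 50, 20.0)
        assert f == 0.0 and r2 == 0.0

    def test_zero_residual_df_rejected(self):
        with pytest.raises(ValueError, match="df_res"):
            assemble_permanova_row(1.0, 1, 1.0, 0, 2.0)


class TestModelFormula:
    def test_parse_and_factors(self):
        f = ModelFormula.parse("tolerance + temperature + tolerance:temperature")
        assert f.terms == ["tolerance", "temperature", "tolerance:temperature"]
        assert f.factors() == ["tolerance", "temperature"]

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelFormula.parse("part + part")
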