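import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from thermogut import (DistanceMatrix, FeatureTable, PairSelector, bray_curtis,
                       distance_contrast, jaccard_presence, pcoa)

from conftest import make_metadata


def table_from(rows, ids=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = [f"f{j}" for j in range(rows.shape[1])]
    return FeatureTable(pd.DataFrame(rows, index=ids, columns=cols))


class TestBrayCurtis:
    def test_hand_values(self):
        dm = bray_curtis(table_from([[6, 2], [2, 2], [6, 2], [5, 0]]))
        assert dm.values[0, 2] == 0.0                      # identical samples
        assert dm.values[0, 1] == pytest.approx(4 / 12)    # |6-2|+|2-2| over 12
        assert dm.values[1, 3] == pytest.approx(5 / 9)

    def test_disjoint_supports_distance_one(self):
        dm = bray_curtis(table_from([[5, 0], [0, 7]]))
        assert dm.values[0, 1] == 1.0

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            bray_curtis(table_from([[0, 0], [1, 1]]))

    def test_presence_coded_equals_sorensen(self):
        """On 0/1 counts Bray-Curtis reduces to the Sorensen set distance."""
        rng = np.random.default_rng(0)
        x = (rng.random((6, 12)) < 0.5).astype(int)
        x[:, 0] = 1  # no empty samples
        dm = bray_curtis(table_from(x))
        for i in range(6):
            for j in range(i + 1, 6):
                a, b = set(np.flatnonzero(x[i])), set(np.flatnonzero(x[j]))
                sorensen = 1 - 2 * len(a & b) / (len(a) + len(b))
                assert dm.values[i, j] == pytest.approx(sorensen, abs=1e-12)


class TestJaccard:
    def test_hand_values(self):
        # A={f0,f1,f2}, B={f2,f3}: 1 - 1/4
        dm = jaccard_presence(table_from([[1, 2, 3, 0], [0, 0, 1, 4]]))
        assert dm.values[0, 1] == pytest.approx(0.75)

    def test_identical_and_disjoint(self):
        dm = jaccard_presence(table_from([[1, 1, 0], [1, 1, 0], [0, 0, 2]]))
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0

    def test_both_empty_distance_zero(self):
        dm = jaccard_presence(table_from([[0, 0], [0, 0]]))
        assert dm.values[0, 1] == 0.0

    def test_detection_threshold(self):
        df = pd.DataFrame([[0.5, 2.0], [0.0, 2.0]], index=["a", "b"],
                          columns=["g1", "g2"])
        assert jaccard_presence(df, detect_threshold=0.0).values[0, 1] == 0.5
        assert jaccard_presence(df, detect_threshold=1.0).values[0, 1] == 0.0


class TestPcoa:
    def test_euclidean_line_recovered(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        ordn = pcoa(DistanceMatrix(["a", "b", "c"], d), k=1)
        rec = squareform(pdist(ordn.coordinates))
        assert np.allclose(rec, d, atol=1e-9)
        assert ordn.proportion_explained[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(1)
        table = table_from(rng.integers(1, 50, size=(8, 15)))
        dm = bray_curtis(table)
        ordn = pcoa(dm)
        from thermogut import gower_center
        g = gower_center(dm)
        total_pos = ordn.eigenvalues.sum() + 0.0
        assert total_pos <= np.trace(g) + ordn.negative_eigenvalue_mass + 1e-9

    def test_full_rank_reconstruction_within_negative_mass(self):
        """Distances among all retained coordinates reproduce Bray-Curtis up
        to the error budget implied by the dropped negative eigenvalues."""
        rng = np.random.default_rng(2)
        table = table_from(rng.integers(0, 40, size=(10, 20)) + 1)
        dm = bray_curtis(table)
        ordn = pcoa(dm)  # all positive axes
        rec = squareform(pdist(ordn.coordinates))
        err = np.abs(rec ** 2 - dm.values ** 2).max()
        assert err <= 4 * ordn.negative_eigenvalue_mass + 1e-9

    def test_matches_skbio(self):
        """Cross-check against the scikit-bio ordination on the same matrix."""
        import skbio
        rng = np.random.default_rng(3)
        table = table_from(rng.integers(1, 30, size=(7, 12)))
        dm = bray_curtis(table)
        ours = pcoa(dm, k=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=dm.ids), method="eigh")
        for axis in range(3):
            a = ours.coordinates[:, axis]
            b = theirs.samples.iloc[:, axis].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_too_many_axes_rejected(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="positive eigenvalues"):
            pcoa(DistanceMatrix(["a", "b"], d), k=2)


class TestDistanceContrast:
    def test_identical_selections_give_t_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.random(8)
        ids = [f"s{i}" for i in range(8)]
        d = np.abs(np.subtract.outer(pts, pts))
        meta = make_metadata(ids, ["resistant"] * 8, ["warm24"] * 8)
        sel = PairSelector(factor="tolerance", mode="within", level="resistant")
        out = distance_contrast(DistanceMatrix(ids, d), meta, sel, sel,
                                n_perm=99, seed=1)
        assert out.t == 0.0
        assert out.p == 1.0

    def test_maximal_separation_minimal_p_in_pair_mode(self):
        """Tight cluster vs spread cluster: with pooled pair relabeling the
        perfectly separated distance sets drive p to its floor 1/(n_perm+1)."""
        ids = [f"r{i}" for i in range(5)] + [f"s{i}" for i in range(5)]
        pts = [0.0, 0.1, 0.2, 0.3, 0.4] + [0.0, 10.0, 20.0, 30.0, 40.0]
        d = np.abs(np.subtract.outer(pts, pts))
        meta = make_metadata(ids, ["resistant"] * 5 + ["sensitive"] * 5,
                             ["warm24"] * 10)
        a = PairSelector(factor="tolerance", mode="within", level="resistant")
        b = PairSelector(factor="tolerance", mode="within", level="sensitive")
        out = distance_contrast(DistanceMatrix(ids, d), meta, a, b,
                                n_perm=999, seed=3, permute="pairs")
        assert out.p == pytest.approx(1 / 1000)
        assert out.corrected_p == pytest.approx(1 / 1000)

    def test_sample_permutation_detects_signal_but_not_floor(self):
        """Sample-level relabeling gives a small but honest p: only
        relabelings reproducing the cluster split match the observed t."""
        ids = [f"r{i}" for i in range(5)] + [f"s{i}" for i in range(5)]
        pts = [0.0, 0.1, 0.2, 0.3, 0.4] + [0.0, 10.0, 20.0, 30.0, 40.0]
        d = np.abs(np.subtract.outer(pts, pts))
        meta = make_metadata(ids, ["resistant"] * 5 + ["sensitive"] * 5,
                             ["warm24"] * 10)
        a = PairSelector(factor="tolerance", mode="within", level="resistant")
        b = PairSelector(factor="tolerance", mode="within", level="sensitive")
        out = distance_contrast(DistanceMatrix(ids, d), meta, a, b,
                                n_perm=999, seed=3)
        assert out.p <= 0.05

    def test_bonferroni_correction(self):
        ids = [f"r{i}" for i in range(4)] + [f"s{i}" for i in range(4)]
        pts = [0.0, 0.1, 0.2, 0.3, 0.0, 5.0, 10.0, 15.0]
        d = np.abs(np.subtract.outer(pts, pts))
        meta = make_metadata(ids, ["resistant"] * 4 + ["sensitive"] * 4,
                             ["warm24"] * 8)
        a = PairSelector(factor="tolerance", mode="within", level="resistant")
        b = PairSelector(factor="tolerance", mode="within", level="sensitive")
        out = distance_contrast(DistanceMatrix(ids, d), meta, a, b,
                                n_perm=199, seed=3, n_comparisons=4)
        assert out.corrected_p == pytest.approx(min(1.0, out.p * 4))

    def test_between_mode_and_stratum(self):
        ids = [f"x{i}" for i in range(6)]
        pts = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        d = np.abs(np.subtract.outer(pts, pts))
        meta = make_metadata(
            ids, ["resistant"] * 3 + ["sensitive"] * 3,
            ["warm24", "cold12"] * 3)
        sel = PairSelector(factor="temperature", mode="between",
                           stratum={"tolerance": "resistant"})
        vals = sel.select(DistanceMatrix(ids, d), meta)
        # resistant samples: x0(warm) x1(cold) x2(warm) -> pairs (x0,x1),(x1,x2)
        assert sorted(vals.tolist()) == [1.0, 1.0]
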