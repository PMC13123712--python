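import numpy as np
import pandas as pd
import pytest

from guildshift import compositional
from guildshift.errors import GuildshiftError
from guildshift.tables import ClrTable, CompositionTable


def comp(rows, totals=None, columns=None):
    df = pd.DataFrame(
        rows,
        index=[f"s{i}" for i in range(len(rows))],
        columns=columns or [f"t{j}" for j in range(len(rows[0]))],
    )
    tot = pd.Series(totals, index=df.index) if totals is not None else None
    return CompositionTable(df, totals=tot)


class TestCzmReplace:
    def test_positive_rows_unchanged(self):
        c = comp([[0.2, 0.3, 0.5]], totals=[100])
        out = compositional.czm_replace(c)
        pd.testing.assert_frame_equal(out.data, c.data)

    def test_replacement_formula(self):
        # delta = 0.65 / (N + 1); nonzeros rescaled multiplicatively
        c = comp([[0.5, 0.5, 0.0]], totals=[100])
        out = compositional.czm_replace(c).data.iloc[0]
        delta = 0.65 / 101
        assert out.iloc[2] == pytest.approx(delta)
        assert out.iloc[0] == pytest.approx(0.5 * (1 - delta))

    def test_closure_preserved(self):
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.full(8, 0.3), size=12).round(3)
        x = x / x.sum(axis=1, keepdims=True)
        c = comp(list(x), totals=[2000] * 12)
        out = compositional.czm_replace(c)
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-12)
        assert (out.data.to_numpy() > 0).all()

    def test_all_zero_row_is_an_error(self):
        df = pd.DataFrame([[0.0, 0.0]], index=["s0"], columns=["a", "b"])
        c = CompositionTable.__new__(CompositionTable)
        c.data, c.totals = df, pd.Series([100], index=["s0"])
        with pytest.raises(GuildshiftError, match="entirely zero"):
            compositional.czm_replace(c)

    def test_large_delta_warns(self):
        c = comp([[0.999, 0.001, 0.0]], totals=[5])
        with pytest.warns(UserWarning, match="delta"):
            compositional.czm_replace(c)


class TestClr:
    def test_equal_parts_map_to_zero(self):
        out = compositional.clr_transform(comp([[1 / 3] * 3]))
        np.testing.assert_allclose(out.data.to_numpy(), 0.0, atol=1e-15)

    def test_geometric_progression(self):
        out = compositional.clr_transform(comp([[1 / 7, 2 / 7, 4 / 7]]))
        np.testing.assert_allclose(
            out.data.to_numpy()[0], [-np.log(2), 0.0, np.log(2)], atol=1e-12
        )

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(6), size=10)
        out = compositional.clr_transform(comp(list(x)))
        np.testing.assert_allclose(out.data.sum(axis=1), 0.0, atol=1e-10)

    def test_zero_entry_directs_to_replacement(self):
        with pytest.raises(GuildshiftError, match="czm_replace"):
            compositional.clr_transform(comp([[0.5, 0.5, 0.0]], totals=[10]))

    def test_matches_reference_clr_implementation(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(5), size=8)
        ours = compositional.clr_transform(comp(list(x))).data.to_numpy()
        np.testing.assert_allclose(ours, skbio_comp.clr(x), atol=1e-10)


def _random_clr(rng, n, k):
    x = rng.normal(size=(n, k))
    x -= x.mean(axis=1, keepdims=True)
    return ClrTable(pd.DataFrame(x, index=[f"s{i}" for i in range(n)]))


class TestAitchisonPca:
    def test_scores_preserve_aitchison_distances(self):
        rng = np.random.default_rng(3)
        clr = _random_clr(rng, 10, 6)
        ordn = compositional.aitchison_pca(clr)
        from scipy.spatial.distance import pdist

        d_scores = pdist(ordn.scores.to_numpy())
        d_clr = pdist(clr.data.to_numpy())
        np.testing.assert_allclose(d_scores, d_clr, atol=1e-8)

    def test_duplicated_sample_gets_identical_scores(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 4))
        x -= x.mean(axis=1, keepdims=True)
        x = np.vstack([x, x[0]])
        clr = ClrTable(pd.DataFrame(x, index=[f"s{i}" for i in range(6)]))
        ordn = compositional.aitchison_pca(clr)
        np.testing.assert_allclose(
            ordn.scores.iloc[0].to_numpy(), ordn.scores.iloc[-1].to_numpy(), atol=1e-8
        )

    def test_variance_fractions_nonincreasing_and_sum_to_one(self):
        rng = np.random.default_rng(5)
        ordn = compositional.aitchison_pca(_random_clr(rng, 12, 7))
        v = ordn.variance_explained
        assert (np.diff(v) <= 1e-12).all()
        assert v.sum() == pytest.approx(1.0, abs=1e-8)

    def test_centroids_are_group_means(self):
        rng = np.random.default_rng(6)
        clr = _random_clr(rng, 8, 5)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=clr.data.index)
        ordn = compositional.aitchison_pca(clr, groups=groups)
        manual = ordn.scores.iloc[:4, :2].mean()
        np.testing.assert_allclose(
            ordn.centroids.loc["a"].to_numpy(), manual.to_numpy(), atol=1e-12
        )

    def test_planted_shift_separates_on_pc1(self):
        rng = np.random.default_rng(7)
        shift = np.array([3.0, -3.0, 3.0, -3.0, 0.0, 0.0])
        x = np.vstack(
            [rng.normal(0, 0.5, (15, 6)), rng.normal(0, 0.5, (15, 6)) + shift]
        )
        x -= x.mean(axis=1, keepdims=True)
        clr = ClrTable(pd.DataFrame(x, index=[f"s{i}" for i in range(30)]))
        ordn = compositional.aitchison_pca(clr)
        pc1 = ordn.scores.iloc[:, 0].to_numpy()
        assert ordn.variance_explained[0] > 0.3
        assert np.sign(pc1[:15]).sum() * np.sign(pc1[15:]).sum() < 0  # split

    def test_needs_three_samples(self):
        rng = np.random.default_rng(8)
        with pytest.raises(GuildshiftError, match="3 samples"):
            compositional.aitchison_pca(_random_clr(rng, 2, 4))


class TestEnvfit:
    def test_disjoint_clusters_reach_minimal_p(self):
        rng = np.random.default_rng(9)
        shift = np.array([4.0, -4.0, 4.0, -4.0, 0.0])
        x = np.vstack(
            [rng.normal(0, 0.3, (12, 5)), rng.normal(0, 0.3, (12, 5)) + shift]
        )
        x -= x.mean(axis=1, keepdims=True)
        clr = ClrTable(pd.DataFrame(x, index=[f"s{i}" for i in range(24)]))
        ordn = compositional.aitchison_pca(clr)
        labels = pd.Series(["a"] * 12 + ["b"] * 12, index=clr.data.index)
        r2, p = compositional.envfit_factor(ordn, labels, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert r2 > 0.9

    def test_identical_groups_give_near_zero_r2(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(30, 4))
        x -= x.mean(axis=1, keepdims=True)
        clr = ClrTable(pd.DataFrame(x, index=[f"s{i}" for i in range(30)]))
        ordn = compositional.aitchison_pca(clr)
        # mirrored labels: both groups share centroid and spread by construction
        labels = pd.Series(rng.permutation(["a", "b"] * 15), index=clr.data.index)
        r2, _ = compositional.envfit_factor(ordn, labels, n_perm=99, seed=1)
        assert abs(r2) < 0.2

    def test_single_group_rejected(self):
        rng = np.random.default_rng(11)
        ordn = compositional.aitchison_pca(_random_clr(rng, 6, 4))
        labels = pd.Series(["a"] * 6, index=ordn.scores.index)
        with pytest.raises(GuildshiftError, match="two groups"):
            compositional.envfit_factor(ordn, labels)


class TestPerturbationInvariance:
    def test_clr_shift_and_distance_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.dirichlet(np.ones(6), size=9)
        pert = rng.uniform(0.5, 2.0, size=6)
        y = x * pert
        y /= y.sum(axis=1, keepdims=True)
        clr_x = compositional.clr_transform(comp(list(x))).data.to_numpy()
        clr_y = compositional.clr_transform(comp(list(y))).data.to_numpy()
        # CLR shifts by a constant per taxon...
        shifts = clr_y - clr_x
        np.testing.assert_allclose(shifts - shifts[0], 0.0, atol=1e-8)
        # ...so Aitchison distances are unchanged
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(clr_x), pdist(clr_y), atol=1e-8)
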