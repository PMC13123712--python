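import numpy as np
import pandas as pd
import pytest

from guildshift import network
from guildshift.errors import GuildshiftError
from guildshift.tables import CompositionTable


def rel_table(rows, columns=None):
    df = pd.DataFrame(
        rows,
        index=[f"s{i}" for i in range(len(rows))],
        columns=columns or [f"t{j}" for j in range(len(rows[0]))],
    )
    df = df.div(df.sum(axis=1), axis=0)
    return CompositionTable(df)


def brute_force_spearman(x: np.ndarray) -> np.ndarray:
    """Independent oracle: average ranks by hand, then Pearson on ranks."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    k = x.shape[1]
    out = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            ra, rb = ranks(x[:, a]), ranks(x[:, b])
            ra -= ra.mean()
            rb -= rb.mean()
            out[a, b] = out[b, a] = (ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb))
    return out


class TestTopTaxa:
    def test_full_ranking_by_mean_abundance(self):
        rel = rel_table([[10, 30, 60], [20, 30, 50]])
        assert network.top_taxa(rel, 3) == ["t2", "t1", "t0"]

    def test_ties_broken_lexicographically(self):
        rel = rel_table([[25, 25, 50]], columns=["zeta", "alpha", "rest"])
        assert network.top_taxa(rel, 2) == ["rest", "alpha"]

    def test_one_spike_outranks_constant_low(self):
        rows = [[50, 2, 48]] + [[0, 2, 98]] * 9
        rel = rel_table(rows, columns=["spike", "low", "bulk"])
        order = network.top_taxa(rel, 3)
        assert order.index("spike") < order.index("low")

    def test_requesting_too_many_taxa_fails(self):
        with pytest.raises(GuildshiftError):
            network.top_taxa(rel_table([[1, 1]]), 3)


class TestCorrelationNetwork:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.integers(0, 20, size=(8, 6)).astype(float) + 1
            rel = rel_table(list(x))
            net = network.correlation_network(rel)
            oracle = brute_force_spearman(rel.data.to_numpy())
            np.testing.assert_allclose(net.rho.to_numpy(), oracle, atol=1e-12)

    def test_invariant_to_monotone_per_taxon_transforms(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.lognormal(size=(12, 5)))
        net_raw = network.correlation_network(x)
        net_log = network.correlation_network(np.log(x))
        np.testing.assert_allclose(
            net_raw.rho.to_numpy(), net_log.rho.to_numpy(), atol=1e-12
        )

    def test_perfectly_monotone_pair(self):
        rows = [[i + 1, 2 * i + 1, 7] for i in range(6)]
        net = network.correlation_network(pd.DataFrame(rows, columns=list("abc")))
        assert net.rho.loc["a", "b"] == pytest.approx(1.0)
        assert net.q.loc["a", "b"] < 0.01

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(2)
        net = network.correlation_network(pd.DataFrame(rng.normal(size=(10, 5))))
        rho = net.rho.to_numpy()
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_zero_variance_taxon_excluded_from_bh_family(self):
        rows = [[1, 5 + (i % 3), i + 1] for i in range(6)]  # 'a' is constant
        net = network.correlation_network(pd.DataFrame(rows, columns=list("abc")))
        assert np.isnan(net.rho.loc["a", "c"])
        assert np.isfinite(net.rho.loc["b", "c"])
        assert net.n_excluded_pairs == 2  # pairs (a,b) and (a,c)


class TestDeltaRho:
    def _net(self, seed, n=8, k=4):
        rng = np.random.default_rng(seed)
        return network.correlation_network(pd.DataFrame(rng.normal(size=(n, k))))

    def test_identical_networks_give_zero_shift(self):
        net = self._net(0)
        cmp_ = network.delta_rho(net, net)
        assert np.allclose(cmp_.delta_rho.to_numpy(), 0.0)
        assert cmp_.wilcoxon_delta[1] == 1.0

    def test_antisymmetric_under_cohort_swap(self):
        a, b = self._net(1), self._net(2)
        ab = network.delta_rho(a, b)
        ba = network.delta_rho(b, a)
        np.testing.assert_allclose(
            ab.delta_rho.to_numpy(), -ba.delta_rho.to_numpy(), atol=1e-12
        )

    def test_top_shifts_ranked_by_magnitude(self):
        a, b = self._net(3), self._net(4)
        shifts = network.delta_rho(a, b).top_shifts["delta_rho"].abs()
        assert (shifts.diff().dropna() <= 1e-12).all()

    def test_too_few_shared_taxa_rejected(self):
        a = self._net(5)
        rng = np.random.default_rng(6)
        b = network.correlation_network(
            pd.DataFrame(rng.normal(size=(8, 3)), columns=["x", "y", "z"])
        )
        with pytest.raises(GuildshiftError, match="shared"):
            network.delta_rho(a, b)


class TestConnectednessAndCohesion:
    def test_uniform_positive_matrix(self):
        taxa = list("abcd")
        rho = pd.DataFrame(0.5, index=taxa, columns=taxa)
        np.fill_diagonal(rho.values, 1.0)
        net = network.CorrelationNetwork(taxa, rho, rho * 0, taxa)
        kappa = network.connectedness(net)
        assert (kappa["connectedness_pos"] == 0.5).all()
        assert (kappa["connectedness_neg"] == 0.0).all()

    def test_mixed_sign_means(self):
        taxa = list("abcd")
        rho = pd.DataFrame(
            [
                [1.0, 0.4, -0.2, 0.8],
                [0.4, 1.0, 0.1, 0.1],
                [-0.2, 0.1, 1.0, 0.1],
                [0.8, 0.1, 0.1, 1.0],
            ],
            index=taxa,
            columns=taxa,
        )
        net = network.CorrelationNetwork(taxa, rho, rho * 0, taxa)
        kappa = network.connectedness(net)
        assert kappa.loc["a", "connectedness_pos"] == pytest.approx(0.6)
        assert kappa.loc["a", "connectedness_neg"] == pytest.approx(-0.2)

    def test_bounds_hold_on_random_networks(self):
        rng = np.random.default_rng(7)
        net = network.correlation_network(pd.DataFrame(rng.normal(size=(15, 8))))
        kappa = network.connectedness(net)
        assert kappa["connectedness_pos"].between(0, 1).all()
        assert kappa["connectedness_neg"].between(-1, 0).all()

    def test_single_taxon_sample_inherits_its_connectedness(self):
        taxa = ["a", "b"]
        rho = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=taxa, columns=taxa)
        net = network.CorrelationNetwork(taxa, rho, rho * 0, taxa)
        kappa = network.connectedness(net)
        rel = rel_table([[1, 0]], columns=taxa)
        coh = network.cohesion(rel, kappa)
        assert coh["cohesion_pos"].iloc[0] == pytest.approx(0.5)

    def test_cohesion_is_linear_in_connectedness(self):
        rng = np.random.default_rng(8)
        rel = rel_table(list(rng.integers(1, 20, size=(6, 4)).astype(float)))
        net = network.correlation_network(rel)
        kappa = network.connectedness(net)
        coh1 = network.cohesion(rel, kappa)
        coh2 = network.cohesion(rel, kappa * 2)
        np.testing.assert_allclose(
            coh2.to_numpy(), 2 * coh1.to_numpy(), atol=1e-12
        )

    def test_uniform_abundance_averages_connectedness(self):
        taxa = list("abc")
        rho = pd.DataFrame(
            [[1.0, 0.6, -0.3], [0.6, 1.0, 0.2], [-0.3, 0.2, 1.0]],
            index=taxa,
            columns=taxa,
        )
        net = network.CorrelationNetwork(taxa, rho, rho * 0, taxa)
        kappa = network.connectedness(net)
        rel = rel_table([[1, 1, 1]], columns=taxa)
        coh = network.cohesion(rel, kappa)
        assert coh["cohesion_pos"].iloc[0] == pytest.approx(
            kappa["connectedness_pos"].mean()
        )


class TestCompareCohesion:
    def test_identical_cohorts_show_no_difference(self):
        rng = np.random.default_rng(9)
        rel = rel_table(list(rng.integers(1, 30, size=(10, 5)).astype(float)))
        net = network.correlation_network(rel)
        res = network.cohesion_result(rel, net)
        out = network.compare_cohesion(res, res)
        assert (out["p"] == 1.0).all()

    def test_single_sample_groups_still_testable(self):
        taxa = ["a", "b"]
        rho = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=taxa, columns=taxa)
        net = network.CorrelationNetwork(taxa, rho, rho * 0, taxa)
        kappa = network.connectedness(net)
        ra = rel_table([[1, 1]], columns=taxa)
        rb = rel_table([[1, 3]], columns=taxa)
        res_a = network.cohesion_result(ra, net)
        res_b = network.cohesion_result(rb, net)
        out = network.compare_cohesion(res_a, res_b)
        assert np.isfinite(out["p"]).all()
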