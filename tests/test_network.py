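"""Contact-network generation: degrees, realization, intensities, noise."""

import numpy as np
import pytest
from scipy import stats

from igesim.network import (
    ContactNetwork,
    add_intensity_noise,
    build_directed_network,
    build_undirected_network,
    sample_degree_sequence,
    sample_intensities,
    simulate_contact_networks,
    split_directed_degrees,
    truncated_poisson_mean,
)


def test_poisson_99_quantile_is_43():
    assert stats.poisson.ppf(0.99, 30) == 43


class TestDegreeSequence:
    def test_truncation_and_even_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = sample_degree_sequence(100, 30, 43, rng=rng)
            assert d.max() <= 43
            assert d.sum() % 2 == 0

    def test_mean_matches_truncated_poisson(self):
        rng = np.random.default_rng(2)
        draws = np.concatenate(
            [sample_degree_sequence(100, 30, 43, rng=rng) for _ in range(50)]
        )
        mu = truncated_poisson_mean(30, 43)
        assert mu < 30  # truncation pulls the mean slightly below 30
        se = draws.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(mu, abs=3 * se)

    def test_small_herd_constraints(self):
        d = sample_degree_sequence(5, 3, 4, seed=3)
        assert d.max() <= 4 and d.sum() % 2 == 0

    def test_max_must_be_below_herd_size(self):
        with pytest.raises(ValueError):
            sample_degree_sequence(40, 30, 43, seed=1)


class TestUndirected:
    def test_two_cows_single_edge(self):
        assert build_undirected_network(np.array([1, 1]), seed=1) == [(0, 1)]

    def test_exact_degree_realization_and_handshake(self):
        rng = np.random.default_rng(4)
        degrees = sample_degree_sequence(100, 30, 43, rng=rng)
        edges = build_undirected_network(degrees, rng=rng)
        assert len(edges) == degrees.sum() // 2
        realized = np.zeros(100, dtype=int)
        for a, b in edges:
            assert a != b
            realized[a] += 1
            realized[b] += 1
        np.testing.assert_array_equal(realized, degrees)
        assert len(set(edges)) == len(edges)  # simple graph

    def test_non_graphical_rejected(self):
        with pytest.raises(ValueError):
            build_undirected_network(np.array([3, 1]), seed=1)


class TestDirected:
    def test_single_arc(self):
        assert build_directed_network(np.array([1, 0]), np.array([0, 1]), seed=1) == [
            (1, 0)
        ]

    def test_split_respects_caps_and_balances(self):
        rng = np.random.default_rng(5)
        total = sample_degree_sequence(100, 30, 43, rng=rng)
        d_in, d_out = split_directed_degrees(total, rng=rng)
        np.testing.assert_array_equal(d_in + d_out, total)
        assert d_in.max() <= 22 and d_out.max() <= 21
        assert d_in.sum() == d_out.sum()

    def test_mean_in_degree_near_15(self):
        rng = np.random.default_rng(6)
        means = []
        for _ in range(30):
            total = sample_degree_sequence(100, 30, 43, rng=rng)
            d_in, _ = split_directed_degrees(total, rng=rng)
            means.append(d_in.mean())
        assert np.mean(means) == pytest.approx(
            truncated_poisson_mean(30, 43) / 2, abs=3 * np.std(means) / np.sqrt(30)
        )

    def test_low_reciprocity(self):
        rng = np.random.default_rng(7)
        total = sample_degree_sequence(100, 30, 43, rng=rng)
        d_in, d_out = split_directed_degrees(total, rng=rng)
        edges = set(build_directed_network(d_in, d_out, rng=rng))
        reciprocal = sum((b, a) in edges for a, b in edges)
        assert reciprocal / len(edges) < 0.3  # density ~0.15 per direction

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_directed_network(np.array([1, 1]), np.array([1, 0]), seed=1)


@pytest.fixture(scope="module")
def big_network(tiny_sim_module=None):
    import igesim

    cfg = igesim.get_scenario(1).scaled(n_herds=10, herd_size=100)
    sim = igesim.simulate_replicate(cfg, 99)
    return sim.network


class TestIntensities:
    def test_standardized_moments(self, big_network):
        net = sample_intensities(big_network, 1.0, 2.0, standardize=True, seed=8)
        f = net.edges["f_true"].to_numpy()
        n = f.size
        assert f.mean() == pytest.approx(1.0, abs=3 * f.std() / np.sqrt(n))
        # var of gamma(1, 2)/0.5 is 1; SE of the variance ~ var * sqrt(2/n)
        assert f.var() == pytest.approx(1.0, abs=3 * np.sqrt(2 / n) * 2)
        assert (f > 0).all()
        assert stats.skew(f) > 1  # right-skewed

    def test_unstandardized_moments(self, big_network):
        net = sample_intensities(big_network, 1.0, 2.0, standardize=False, seed=9)
        f = net.edges["f_true"].to_numpy()
        n = f.size
        assert f.mean() == pytest.approx(0.5, abs=3 * f.std() / np.sqrt(n))
        assert f.std() == pytest.approx(0.5, rel=0.05)

    def test_noise_attenuation(self, big_network):
        net = sample_intensities(big_network, seed=10)
        noisy = add_intensity_noise(net, 0.16, seed=11)
        f_true = noisy.edges["f_true"].to_numpy()
        f_obs = noisy.edges["f_analysis"].to_numpy()
        n = f_true.size
        diff_var = (f_obs - f_true).var()
        assert diff_var == pytest.approx(0.16, abs=3 * 0.16 * np.sqrt(2 / n))
        # corr(true, noisy) = 1/sqrt(1 + noise/var) ~ 0.93 for var 1
        expected = 1 / np.sqrt(1.16)
        assert np.corrcoef(f_true, f_obs)[0, 1] == pytest.approx(expected, abs=0.01)

    def test_zero_noise_is_identity(self, big_network):
        net = sample_intensities(big_network, seed=12)
        noisy = add_intensity_noise(net, 0.0, seed=13)
        np.testing.assert_array_equal(
            noisy.edges["f_true"].to_numpy(), noisy.edges["f_analysis"].to_numpy()
        )

    def test_negative_noise_rejected(self, big_network):
        with pytest.raises(ValueError):
            add_intensity_noise(big_network, -0.1, seed=1)


class TestHerdNetworks:
    def test_incoming_counts_undirected(self, tiny_sim):
        counts = tiny_sim.network.incoming_counts()
        e = tiny_sim.network.edges
        assert counts.sum() == 2 * len(e)
        assert counts.max() <= 43

    def test_all_edges_within_herd(self, tiny_sim):
        net = tiny_sim.network
        herd = net.cow_herd
        e = net.edges
        assert (herd.loc[e["source"]].to_numpy() == e["herd"].to_numpy()).all()
        assert (herd.loc[e["target"]].to_numpy() == e["herd"].to_numpy()).all()

    def test_directed_caps(self):
        import igesim

        cfg = igesim.get_scenario(21).scaled(n_herds=2, herd_size=60)
        sim = igesim.simulate_replicate(cfg, 5)
        net = sim.network
        assert net.directed
        incoming = net.incoming_counts()
        outgoing = net.edges["source"].value_counts()
        assert incoming.max() <= 22
        assert outgoing.max() <= 21
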