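"""Cross-correlations, phi(r), correlation length, and susceptibility."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from critnet import (
    CorrelationProfile,
    build_kirchhoff,
    correlation_function,
    correlation_length,
    covariance_from_network,
    cross_correlation,
    generate_fcc_cluster,
    generate_ideal_chain,
    group_average,
    pair_distances,
    radius_of_gyration,
    rescale_profile,
    run_structure,
    shape_factor,
    susceptibility,
    build_lattice_springs,
)


def _profile(centers, phi, counts=None, width=None):
    centers = np.asarray(centers, dtype=float)
    if width is None:
        width = centers[1] - centers[0] if len(centers) > 1 else 1.0
    if counts is None:
        counts = np.ones(len(centers), dtype=int)
    return CorrelationProfile(
        bin_centers=centers,
        phi=np.asarray(phi, dtype=float),
        counts=np.asarray(counts),
        bin_width=float(width),
    )


class TestCrossCorrelation:
    def test_unit_diagonal(self):
        chain = generate_ideal_chain(25, seed=3)
        cov = covariance_from_network(build_kirchhoff(chain, r_cut=9.0))
        phi = cross_correlation(cov)
        np.testing.assert_allclose(np.diag(phi), 1.0)
        assert np.all(np.abs(phi) <= 1.0)

    def test_identity_covariance(self):
        np.testing.assert_array_equal(cross_correlation(np.eye(5)), np.eye(5))

    def test_p3_brute_force(self, p3_network):
        c = covariance_from_network(p3_network).values
        phi = cross_correlation(covariance_from_network(p3_network))
        n = c.shape[0]
        for i in range(n):
            for j in range(n):
                expected = c[i, j] / np.sqrt(c[i, i] * c[j, j])
                assert phi[i, j] == pytest.approx(np.clip(expected, -1, 1), abs=1e-12)

    def test_bad_diagonal_named(self):
        c = np.eye(4)
        c[2, 2] = -1.0
        with pytest.raises(ValueError, match="nodes \\[2\\]"):
            cross_correlation(c)


class TestCorrelationFunction:
    def test_constant_phi(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        phi = np.full((4, 4), 0.7)
        prof = correlation_function(phi, pair_distances(pts), bin_width=5.0)
        occ = prof.occupied
        assert occ.sum() == 1
        assert prof.phi[occ][0] == pytest.approx(0.7)

    def test_pair_on_bin_edge_goes_up(self):
        pts = np.array([[0, 0, 0], [6.0, 0, 0]])
        phi = np.full((2, 2), 0.5)
        prof = correlation_function(phi, pair_distances(pts), bin_width=2.0)
        # r = 6 with 2 A bins: bin [6, 8), center 7
        assert prof.counts[3] == 1
        assert prof.bin_centers[3] == pytest.approx(7.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_pair_loop(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 15, size=(10, 3))
        m = rng.uniform(-1, 1, size=(10, 10))
        phi = (m + m.T) / 2
        np.fill_diagonal(phi, 1.0)
        dist = pair_distances(pts)
        w = 2.5
        prof = correlation_function(phi, dist, bin_width=w)
        sums, counts = {}, {}
        for i in range(10):
            for j in range(i + 1, 10):
                k = int(dist[i, j] // w)
                sums[k] = sums.get(k, 0.0) + phi[i, j]
                counts[k] = counts.get(k, 0) + 1
        for k, c in counts.items():
            assert prof.counts[k] == c
            assert prof.phi[k] == pytest.approx(sums[k] / c)


class TestCorrelationLength:
    def test_interpolated_crossing(self):
        prof = _profile([2, 6, 10], [0.5, 0.1, -0.2], width=4.0)
        xi = correlation_length(prof)
        assert not xi.censored
        assert xi.value == pytest.approx(6 + 4 * (0.1 / 0.3))

    def test_all_positive_censored(self):
        prof = _profile([2, 6, 10], [0.5, 0.3, 0.1], width=4.0)
        xi = correlation_length(prof)
        assert xi.censored and xi.value == pytest.approx(10.0)

    def test_exact_zero_bin(self):
        prof = _profile([2, 6, 10], [0.5, 0.0, -0.2], width=4.0)
        xi = correlation_length(prof)
        assert not xi.censored and xi.value == pytest.approx(6.0)

    def test_needs_two_bins(self):
        with pytest.raises(ValueError, match="2 occupied"):
            correlation_length(_profile([2.0], [0.5]))


class TestSusceptibility:
    def test_all_correlated(self):
        n = 8
        pts = np.random.default_rng(0).uniform(0, 3, size=(n, 3))
        chi = susceptibility(np.ones((n, n)), pair_distances(pts), xi=100.0, s=1.0, n=n)
        assert chi == pytest.approx((n - 1) / 2)

    def test_xi_below_min_distance(self):
        pts = np.array([[0, 0, 0], [5.0, 0, 0], [0, 5.0, 0]])
        chi = susceptibility(np.ones((3, 3)), pair_distances(pts), xi=1.0, s=1.0, n=3)
        assert chi == 0.0

    def test_strict_cut_and_pair_loop(self, rng):
        pts = rng.uniform(0, 12, size=(10, 3))
        m = rng.uniform(-1, 1, size=(10, 10))
        phi = (m + m.T) / 2
        dist = pair_distances(pts)
        xi, s = float(np.median(dist)), 1.7
        expected = sum(
            s / 10 * phi[i, j]
            for i in range(10)
            for j in range(i + 1, 10)
            if dist[i, j] < xi
        )
        assert susceptibility(phi, dist, xi, s, 10) == pytest.approx(expected)
        # a pair moved to exactly xi drops out of the sum (strict Heaviside)
        d2 = dist.copy()
        d2[0, 1] = d2[1, 0] = xi
        expected2 = sum(
            s / 10 * phi[i, j]
            for i in range(10)
            for j in range(i + 1, 10)
            if d2[i, j] < xi
        )
        assert susceptibility(phi, d2, xi, s, 10) == pytest.approx(expected2)


class TestGroupAverage:
    def test_single_member_identity(self):
        prof = _profile([0.5, 1.5], [0.8, -0.1], counts=[3, 4], width=1.0)
        out = group_average([prof], [12.0], rg_bin_center=12.0)
        np.testing.assert_allclose(out.phi, prof.phi)
        np.testing.assert_array_equal(out.counts, prof.counts)

    def test_two_member_mean(self):
        p1 = _profile([0.5, 1.5], [0.6, 0.2], width=1.0)
        p2 = _profile([0.5, 1.5], [0.2, -0.2], width=1.0)
        out = group_average([p1, p2], [11.8, 12.3], rg_bin_center=12.0)
        np.testing.assert_allclose(out.phi, [0.4, 0.0])

    def test_half_open_window(self):
        p = _profile([0.5], [0.5], width=1.0)
        # Rg = 12.5 belongs to the 13 A window, not the 12 A one
        with pytest.raises(ValueError, match="available Rg range"):
            group_average([p], [12.5], rg_bin_center=12.0)
        assert group_average([p], [12.5], rg_bin_center=13.0) is not None


class TestOnNetworks:
    def test_short_range_correlation_positive(self):
        for seed in (0, 1):
            chain = generate_ideal_chain(120, seed=seed)
            cov = covariance_from_network(build_kirchhoff(chain, r_cut=9.0))
            phi = cross_correlation(cov)
            prof = correlation_function(phi, pair_distances(chain.points))
            first = prof.phi[prof.occupied][0]
            assert 0 < first <= 1

    def test_xi_over_rg_constant_for_fcc(self):
        ratios = []
        for n in (100, 200, 400, 800, 1600):
            cluster = generate_fcc_cluster(n)
            net = build_lattice_springs(cluster, shells=2)
            phi = cross_correlation(covariance_from_network(net))
            prof = correlation_function(phi, pair_distances(cluster.points))
            xi = correlation_length(prof)
            assert not xi.censored
            ratios.append(xi.value / radius_of_gyration(cluster))
        ratios = np.array(ratios)
        assert ratios.std() / ratios.mean() < 0.25

    def test_chi_grows_with_chain_length(self):
        means = []
        for n in (50, 100, 200):
            chis = [run_structure(generate_ideal_chain(n, seed=s)).chi for s in range(6)]
            chis = [c for c in chis if c is not None]
            assert chis
            means.append(np.mean(chis))
        assert means[0] < means[1] < means[2]

    def test_rescaled_profile_axis(self):
        prof = _profile([0.5, 1.5, 2.5], [0.5, 0.2, -0.1], width=1.0)
        scaled = rescale_profile(prof, rg=2.0)
        np.testing.assert_allclose(scaled.bin_centers, [0.25, 0.75, 1.25])
        assert scaled.rescaled
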