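import numpy as np
import pytest
from scipy.integrate import solve_ivp

from foldonkinetics.free_energy import FreeEnergyTable
from foldonkinetics.network import (
    DisconnectedNetworkError,
    NetworkError,
    build_connectivity,
    build_rate_matrix,
    chevron_scan,
    connected_components,
    propagate,
    relaxation_rate,
    spectral_solve,
)
from tests.conftest import random_table


def two_state_table(df, temperature=1.0):
    return FreeEnergyTable(
        temperature=temperature, entries={"0": 0.0, "1": df}, gauge="0"
    )


class TestConnectivity:
    def test_hamming_one_pair(self):
        assert build_connectivity({"0000", "0001"}) == [("0000", "0001")]

    def test_hamming_four_no_edge(self):
        assert build_connectivity({"0101", "1010"}) == []

    def test_full_cube_n3(self):
        labels = [format(k, "03b") for k in range(8)]
        edges = build_connectivity(labels)
        # brute-force pairwise Hamming oracle
        brute = sum(
            1
            for i in range(8)
            for j in range(i + 1, 8)
            if sum(a != b for a, b in zip(labels[i], labels[j])) == 1
        )
        assert len(edges) == brute == 12

    def test_mixed_lengths(self):
        with pytest.raises(NetworkError, match="mixed"):
            build_connectivity({"01", "001"})

    def test_unsampled_absent(self):
        edges = build_connectivity({"00", "11"})
        assert edges == []


class TestBuildRateMatrix:
    def test_downhill_rate_is_k0(self):
        K = build_rate_matrix(two_state_table(-2.0), k0=1.0)
        assert K.matrix[K.index("1"), K.index("0")] == 1.0  # 0 -> 1 downhill

    def test_uphill_boltzmann_penalty(self):
        K = build_rate_matrix(two_state_table(2.0), k0=1.0)
        assert K.matrix[K.index("1"), K.index("0")] == pytest.approx(
            np.exp(-2.0)
        )

    def test_detailed_balance_random_tables(self, rng):
        for _ in range(20):
            table = random_table(rng, 4)
            K = build_rate_matrix(table, k0=1.0)
            pi = K.equilibrium()
            flux = K.matrix * pi[None, :]
            assert np.max(np.abs(flux - flux.T)) < 1e-12

    def test_columns_sum_to_zero(self, rng):
        K = build_rate_matrix(random_table(rng, 3), k0=1e6)
        np.testing.assert_allclose(K.matrix.sum(axis=0), 0.0, atol=1e-12 * 1e6)

    def test_validate_passes(self, rng):
        build_rate_matrix(random_table(rng, 4), k0=1e6).validate()

    def test_k0_positive_required(self):
        with pytest.raises(NetworkError):
            build_rate_matrix(two_state_table(0.0), k0=0.0)


class TestSpectralSolve:
    def test_two_state_symmetric(self):
        K = build_rate_matrix(two_state_table(0.0), k0=1.0)
        d = spectral_solve(K)
        np.testing.assert_allclose(d.eigenvalues, [0.0, -2.0], atol=1e-12)

    def test_two_state_analytic_eigenvalue(self):
        # dF = -1: rates k0 down, k0*e^-1 up; nonzero mode -k0(1 + e^-1)
        K = build_rate_matrix(two_state_table(-1.0), k0=1.0)
        d = spectral_solve(K)
        assert d.eigenvalues[1] == pytest.approx(-(1.0 + np.exp(-1.0)),
                                                 rel=1e-12)

    def test_zero_mode_is_boltzmann(self, rng):
        K = build_rate_matrix(random_table(rng, 4), k0=1.0)
        d = spectral_solve(K)
        v0 = d.modes[:, 0]
        v0 = v0 / v0.sum()
        np.testing.assert_allclose(v0, K.equilibrium(), atol=1e-10)

    def test_spectrum_real_nonpositive(self, rng):
        for _ in range(10):
            K = build_rate_matrix(random_table(rng, 5), k0=1.0)
            d = spectral_solve(K)
            assert np.all(d.eigenvalues <= 1e-10)
            assert d.eigenvalues[0] == pytest.approx(0.0, abs=1e-10)

    def test_non_detailed_balance_fallback_warns(self):
        from foldonkinetics.network import RateMatrix

        m = np.array([[-1.0, 0.5], [1.0, -0.5]])
        m[0, 1] = 2.0  # break detailed balance w.r.t. stored free energies
        m[1, 1] = -2.0
        K = RateMatrix(
            labels=("0", "1"), matrix=m, k0=1.0, temperature=1.0,
            free_energies=np.array([0.0, -1.0]),
        )
        with pytest.warns(UserWarning, match="detailed balance"):
            spectral_solve(K)


class TestPropagate:
    def test_t0_returns_p0(self, rng):
        K = build_rate_matrix(random_table(rng, 3), k0=1.0)
        d = spectral_solve(K)
        p0 = rng.dirichlet(np.ones(K.n_states))
        pops = propagate(d, p0, [0.0])
        np.testing.assert_allclose(pops[0], p0, atol=1e-10)

    def test_long_time_is_boltzmann(self, rng):
        K = build_rate_matrix(random_table(rng, 3), k0=1.0)
        d = spectral_solve(K)
        p0 = np.zeros(K.n_states)
        p0[0] = 1.0
        pops = propagate(d, p0, [1e6])
        np.testing.assert_allclose(pops[0], K.equilibrium(), atol=1e-8)

    def test_two_state_single_exponential(self):
        K = build_rate_matrix(two_state_table(-1.0), k0=1.0)
        d = spectral_solve(K)
        pi = K.equilibrium()
        lam = 1.0 + np.exp(-1.0)
        times = np.linspace(0, 5, 20)
        pops = propagate(d, np.array([1.0, 0.0]), times)
        i_u = K.index("0")
        expected = pi[i_u] + (1.0 - pi[i_u]) * np.exp(-lam * times)
        np.testing.assert_allclose(pops[:, i_u], expected, atol=1e-12)

    def test_conservation_all_times(self, rng):
        K = build_rate_matrix(random_table(rng, 4), k0=1.0)
        d = spectral_solve(K)
        p0 = rng.dirichlet(np.ones(K.n_states))
        pops = propagate(d, p0, np.logspace(-3, 3, 25))
        np.testing.assert_allclose(pops.sum(axis=1), 1.0, atol=1e-10)

    def test_ode_oracle_agreement(self, rng):
        for _ in range(5):
            K = build_rate_matrix(random_table(rng, 4), k0=1.0)
            d = spectral_solve(K)
            p0 = rng.dirichlet(np.ones(K.n_states))
            times = np.linspace(0.0, 10.0, 7)
            pops = propagate(d, p0, times)
            sol = solve_ivp(
                lambda t, p: K.matrix @ p, (0.0, times[-1]), p0,
                t_eval=times, rtol=1e-11, atol=1e-12, method="LSODA",
            )
            assert np.max(np.abs(pops.T - sol.y)) < 1e-8

    def test_invalid_populations(self, rng):
        K = build_rate_matrix(random_table(rng, 2), k0=1.0)
        d = spectral_solve(K)
        with pytest.raises(NetworkError):
            propagate(d, np.array([0.5, 0.6, 0.1, 0.0]) * 0 + 0.3, [1.0])


class TestRelaxationRate:
    def test_two_state_df_zero(self):
        K = build_rate_matrix(two_state_table(0.0), k0=1.0)
        r = relaxation_rate(spectral_solve(K))
        assert r.k_obs == pytest.approx(2.0, rel=1e-12)

    def test_deep_stability_saturates_at_k0(self):
        K = build_rate_matrix(two_state_table(-40.0), k0=1.0)
        r = relaxation_rate(spectral_solve(K))
        assert r.k_obs == pytest.approx(1.0, rel=1e-12)

    def test_matches_ode_relaxation_fit(self, rng):
        # oracle: integrate dP/dt = K P numerically and fit the decay rate.
        # Seeding the initial condition along the slowest mode keeps faster
        # modes out of the fit window, so the fitted rate isolates k_obs.
        K = build_rate_matrix(random_table(rng, 4, spread=1.0), k0=1.0)
        d = spectral_solve(K)
        r = relaxation_rate(d)
        pi = K.equilibrium()
        p0 = pi + 0.05 * d.modes[:, 1] / np.max(np.abs(d.modes[:, 1]))
        p0 = np.clip(p0, 1e-9, None)
        p0 /= p0.sum()
        t1, t2 = 1.0 / r.k_obs, 3.0 / r.k_obs
        sol = solve_ivp(
            lambda t, p: K.matrix @ p, (0.0, t2), p0, t_eval=[t1, t2],
            rtol=1e-12, atol=1e-14, method="LSODA",
        )
        dev = np.abs(sol.y - pi[:, None]).sum(axis=0)
        fitted = np.log(dev[0] / dev[1]) / (t2 - t1)
        assert fitted == pytest.approx(r.k_obs, rel=1e-4)

    def test_disconnected_error(self):
        table = FreeEnergyTable(
            temperature=1.0, entries={"00": 0.0, "11": -1.0}, gauge="00"
        )
        K = build_rate_matrix(table, k0=1.0)
        with pytest.raises(DisconnectedNetworkError) as exc:
            relaxation_rate(spectral_solve(K))
        assert exc.value.components == [["00"], ["11"]]

    def test_components_listing(self):
        comps = connected_components(["000", "001", "110", "111"])
        assert comps == [["000", "001"], ["110", "111"]]


class TestChevronScan:
    def test_single_foldon_exact_v(self):
        dfs = np.linspace(-10, 10, 41)
        tables = [two_state_table(df, temperature=1.0 + 1e-3 * k)
                  for k, df in enumerate(dfs)]
        curve = chevron_scan(tables, k0=1.0)
        for (x, y) in curve.points:
            expected = 1.0 + np.exp(-abs(x))
            assert 10.0**y == pytest.approx(expected, rel=1e-10)
        # barrierless one-foldon model: single extremum (maximum) at dF = 0,
        # both arms saturating at k0
        ys = curve.log10_rates
        assert np.argmax(ys) == len(ys) // 2
        assert 10.0 ** ys[0] == pytest.approx(1.0, rel=1e-4)

    def test_k0_linearity(self):
        tables = [two_state_table(df, temperature=1.0 + 1e-3 * k)
                  for k, df in enumerate(np.linspace(-3, 3, 7))]
        c1 = chevron_scan(tables, k0=1.0)
        c2 = chevron_scan(tables, k0=2.0)
        np.testing.assert_allclose(
            c2.log10_rates - c1.log10_rates, np.log10(2.0), atol=1e-12
        )

    def test_synthetic_minimum_near_zero_stability(self):
        from foldonkinetics.synthetic import (
            cooperative_landscape,
            exact_free_energies,
        )

        land = cooperative_landscape(4)
        temps = np.linspace(0.75, 1.45, 25)
        tables = [exact_free_energies(land, t) for t in temps]
        curve = chevron_scan(tables, k0=1.0)
        xs, ys = curve.stabilities, curve.log10_rates
        i = int(np.argmin(ys))
        assert 0 < i < len(ys) - 1  # interior V minimum
        grid_step = np.max(np.diff(xs))
        assert abs(xs[i]) <= grid_step

    def test_skipped_temperatures_reported(self):
        missing = FreeEnergyTable(
            temperature=2.0, entries={"0": 0.0}, gauge="0"
        )
        tables = [two_state_table(-1.0, 1.0), two_state_table(1.0, 1.1),
                  missing]
        curve = chevron_scan(tables, k0=1.0)
        assert curve.skipped == (2.0,)
        assert len(curve.points) == 2
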