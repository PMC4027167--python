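import numpy as np
import pytest
from scipy.optimize import brentq

from napring.deer import (DIPOLAR_CONSTANT_MHZ_NM3, DeerTrace,
                          DistanceDistribution, SpinTopology,
                          assign_symmetric_distances, default_r_grid,
                          default_t_grid, dipolar_kernel, fit_background,
                          fit_deer, find_distribution_peaks, modal_distance,
                          modulation_depth, oscillation_period, read_trace,
                          simulate_trace, tikhonov_invert, write_trace)
from napring.errors import InsufficientTailError, TopologyError


def kernel_quadrature(t, r, n=200001):
    """Independent fine-grid quadrature oracle for the dipolar kernel."""
    x = np.linspace(0.0, 1.0, n)
    nu = DIPOLAR_CONSTANT_MHZ_NM3 / r ** 3
    return np.trapezoid(np.cos(2 * np.pi * nu * (1 - 3 * x ** 2) * t), x)


class TestKernel:
    def test_zero_time_is_one(self):
        r = default_r_grid()
        K = dipolar_kernel(np.array([0.0]), r)
        assert np.all(K == 1.0)

    @pytest.mark.parametrize("r0", [1.5, 2.0, 4.5, 7.8, 12.0])
    @pytest.mark.parametrize("t0", [0.1, 1.0, 7.5, 15.0])
    def test_matches_fine_grid_quadrature(self, r0, t0):
        K = dipolar_kernel(np.array([t0]), np.array([r0]))[0, 0]
        assert K == pytest.approx(kernel_quadrature(t0, r0), abs=1e-8)

    def test_frequency_at_2nm(self):
        # perpendicular dipolar frequency at 2 nm is 52.04/8 = 6.505 MHz
        nu = DIPOLAR_CONSTANT_MHZ_NM3 / 2.0 ** 3
        assert nu == pytest.approx(6.505)

    def test_columns_bounded(self):
        K = dipolar_kernel(default_t_grid(15.0, 0.05), default_r_grid())
        assert K.max() <= 1.0 + 1e-12
        assert K.min() >= -0.5 - 1e-12

    def test_long_distance_completes_oscillation_in_window(self):
        # at 7.8 nm the full oscillation period fits inside 15 μs
        assert oscillation_period(7.8) < 15.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            dipolar_kernel(np.array([1.0]), np.array([-2.0]))


class TestModulationDepth:
    @pytest.mark.parametrize("n,lam,expected", [
        (1, 0.4, 0.0),
        (2, 0.3, 0.30),
        (4, 0.3, 1 - 0.7 ** 3),
        (4, 0.5, 1 - 0.5 ** 3),
    ])
    def test_closed_form(self, n, lam, expected):
        assert modulation_depth(n, lam) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n_spins", [2, 4])
    @pytest.mark.parametrize("lam", [0.1, 0.3, 0.5])
    def test_simulated_trace_obeys_multispin_law(self, n_spins, lam):
        """Read the depth directly off a noiseless trace at a kernel zero.

        With every pair class sharing one sharp distance r0 and no
        background, V(t*) = (1-λ)^(n-1) exactly at any t* where K(t*,r0)=0.
        """
        r = default_r_grid(2.0, 6.0, 0.05)
        r0 = 4.0
        k_of_t = lambda t: dipolar_kernel(np.array([t]), np.array([r0]))[0, 0]
        # bracket the kernel's first sign change, then root-find
        scan = np.linspace(0.01, 2.0 * oscillation_period(r0), 2000)
        kv = np.array([k_of_t(t) for t in scan])
        i = int(np.flatnonzero(np.sign(kv[:-1]) != np.sign(kv[1:]))[0])
        t_star = brentq(k_of_t, scan[i], scan[i + 1])
        t_grid = np.unique(np.concatenate([np.linspace(0, 3.0, 301), [t_star]]))
        topo = SpinTopology(n_spins)
        comps = {label: DistanceDistribution.delta(r0, r)
                 for label in topo.pair_classes}
        trace = simulate_trace(comps, topo, lam, background_rate=0.0,
                               noise_sd=0.0, t_grid=t_grid)
        measured = 1.0 - trace.V[np.searchsorted(t_grid, t_star)]
        assert measured == pytest.approx(modulation_depth(n_spins, lam),
                                         abs=1e-6)


class TestSimulate:
    def test_lambda_zero_invalid_but_background_pure_at_tiny_lambda(self):
        r = default_r_grid(2.0, 6.0, 0.1)
        with pytest.raises(ValueError):
            simulate_trace({"AB": DistanceDistribution.delta(4.0, r)},
                           SpinTopology(2), 0.0)

    def test_missing_pair_component_raises(self):
        r = default_r_grid(2.0, 6.0, 0.1)
        with pytest.raises(TopologyError):
            simulate_trace({"AB": DistanceDistribution.delta(4.0, r)},
                           SpinTopology(4), 0.3)

    def test_equivalent_pair_labels_accepted(self):
        r = default_r_grid(2.0, 6.0, 0.1)
        P = DistanceDistribution.delta(4.0, r)
        t = default_t_grid(2.0, 0.05)
        a = simulate_trace({"AB": P, "AC": P, "AD": P}, SpinTopology(4), 0.3,
                           t_grid=t)
        b = simulate_trace({"CD": P, "BD": P, "BC": P}, SpinTopology(4), 0.3,
                           t_grid=t)
        assert np.allclose(a.V, b.V)

    def test_four_spin_modulation_deeper_than_two_spin(self):
        r = default_r_grid(2.0, 8.0, 0.05)
        P = DistanceDistribution.gaussian(4.5, 0.3, r)
        t = default_t_grid(10.0, 0.02)
        two = simulate_trace({"AB": P}, SpinTopology(2), 0.3, t_grid=t)
        four = simulate_trace({"AB": P, "AC": P, "AD": P}, SpinTopology(4),
                              0.3, t_grid=t)
        assert four.V.min() < two.V.min()
        assert 1 - four.V[-1] > 1 - two.V[-1]


class TestBackground:
    def test_pure_exponential_recovered_exactly(self):
        t = default_t_grid(10.0, 0.02)
        V = np.exp(-0.07 * t)
        bg, F = fit_background(DeerTrace(t, V))
        assert bg.rate == pytest.approx(0.07, abs=1e-6)
        assert np.allclose(F.V, 1.0, atol=1e-9)

    def test_known_rate_recovered_from_modulated_trace(self):
        r = default_r_grid(2.0, 8.0, 0.05)
        P = DistanceDistribution.gaussian(4.0, 0.3, r)
        trace = simulate_trace({"AB": P}, SpinTopology(2), 0.3,
                               background_rate=0.05,
                               t_grid=default_t_grid(15.0, 0.016))
        bg, _ = fit_background(trace)
        assert bg.rate == pytest.approx(0.05, rel=0.05)

    def test_noise_only_form_factor_is_flat(self):
        rng = np.random.default_rng(0)
        t = default_t_grid(10.0, 0.02)
        V = np.exp(-0.05 * t) + rng.normal(0, 0.005, t.size)
        V /= V[0]
        bg, F = fit_background(DeerTrace(t, V))
        assert np.abs(F.V - 1.0).max() < 0.05

    def test_short_tail_rejected(self):
        t = np.linspace(0, 1.0, 6)
        with pytest.raises(InsufficientTailError):
            fit_background(DeerTrace(t, np.exp(-t)), fit_start_fraction=0.99)


class TestInversion:
    def test_sharp_distance_recovered_on_grid(self):
        r = default_r_grid(2.0, 8.0, 0.05)
        P0 = DistanceDistribution.delta(5.0, r)
        trace = simulate_trace({"AB": P0}, SpinTopology(2), 0.3,
                               background_rate=0.05,
                               t_grid=default_t_grid(15.0, 0.016))
        fit = fit_deer(trace, r)
        assert abs(modal_distance(fit.P) - 5.0) <= 0.05
        assert fit.mod_depth == pytest.approx(0.3, abs=0.02)
        area = np.trapezoid(fit.P.P, fit.P.r)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_mean_recovered(self):
        r = default_r_grid(2.0, 8.0, 0.05)
        P0 = DistanceDistribution.gaussian(4.0, 0.3, r)
        trace = simulate_trace({"AB": P0}, SpinTopology(2), 0.3,
                               background_rate=0.05,
                               t_grid=default_t_grid(15.0, 0.016))
        fit = fit_deer(trace, r, alpha="auto")
        assert fit.P.mean() == pytest.approx(4.0, abs=0.1)

    def test_four_spin_components_resolved(self):
        r = default_r_grid(2.0, 10.5, 0.05)
        comps = {"AB": DistanceDistribution.gaussian(6.0, 0.25, r),
                 "AC": DistanceDistribution.gaussian(3.5, 0.25, r),
                 "AD": DistanceDistribution.gaussian(8.0, 0.3, r)}
        trace = simulate_trace(comps, SpinTopology(4), 0.3,
                               background_rate=0.05,
                               t_grid=default_t_grid(15.0, 0.016))
        fit = fit_deer(trace, r)
        peaks = find_distribution_peaks(fit.P, rel_height=0.1)
        for target in (3.5, 6.0, 8.0):
            assert np.min(np.abs(peaks - target)) < 0.35

    def test_residual_monotone_in_alpha(self):
        r = default_r_grid(2.0, 8.0, 0.1)
        P0 = DistanceDistribution.gaussian(4.0, 0.4, r)
        trace = simulate_trace({"AB": P0}, SpinTopology(2), 0.3,
                               t_grid=default_t_grid(8.0, 0.04))
        bg, F = fit_background(trace)
        residuals = [tikhonov_invert(F, r, alpha=a).residual_norm
                     for a in (0.01, 0.1, 1.0, 10.0, 100.0)]
        assert all(b >= a - 1e-12 for a, b in zip(residuals, residuals[1:]))


class TestModalAndAssignment:
    def test_delta_and_tie_breaking(self):
        r = default_r_grid(2.0, 10.0, 0.1)
        assert modal_distance(DistanceDistribution.delta(7.8, r)) == \
            pytest.approx(7.8, abs=0.05)
        # bimodal with equal peaks resolves to the smaller distance
        P = np.zeros_like(r)
        P[10] = 1.0
        P[40] = 1.0
        assert modal_distance(DistanceDistribution(r, P)) == pytest.approx(
            r[10])

    def test_flat_distribution_warns(self):
        r = default_r_grid(2.0, 4.0, 0.1)
        with pytest.warns(UserWarning):
            modal_distance(DistanceDistribution(r, np.ones_like(r)))

    def _dist(self, r, peaks, widths=0.15):
        P = np.zeros_like(r)
        for p in np.atleast_1d(peaks):
            P += np.exp(-0.5 * ((r - p) / widths) ** 2)
        return DistanceDistribution(r, P)

    def test_paper_style_assignment(self):
        # dimer mode 8.5; tetramer adds a short AC and a long AD at 9.1
        r = default_r_grid(2.0, 11.0, 0.05)
        P_dim = self._dist(r, 8.5)
        P_tet = self._dist(r, [4.2, 8.5, 9.6])
        labels = {round(a.r, 1): a.label
                  for a in assign_symmetric_distances(P_dim, P_tet, 0.3)}
        assert labels[8.5] == "AB"
        assert labels[4.2] == "AC"
        assert labels[9.6] == "AD"

    def test_identical_distributions_all_ab(self):
        r = default_r_grid(2.0, 11.0, 0.05)
        P = self._dist(r, [5.0, 8.0])
        out = assign_symmetric_distances(P, P, 0.3)
        assert all(a.label == "AB" for a in out)

    def test_single_new_peak_marks_ad_tentative(self):
        r = default_r_grid(2.0, 11.0, 0.05)
        P_dim = self._dist(r, 8.5)
        P_tet = self._dist(r, [4.2, 8.5])
        out = assign_symmetric_distances(P_dim, P_tet, 0.3)
        by_label = {a.label: a for a in out}
        assert by_label["AC"].r == pytest.approx(4.2, abs=0.1)
        assert by_label["AD"].tentative
        assert "overlaps" in by_label["AD"].note

    def test_no_match_flags_everything(self):
        r = default_r_grid(2.0, 11.0, 0.05)
        out = assign_symmetric_distances(self._dist(r, 8.5),
                                         self._dist(r, 4.0), 0.3)
        assert all(a.tentative for a in out)


def test_trace_file_round_trip(tmp_path):
    t = default_t_grid(5.0, 0.05)
    rng = np.random.default_rng(1)
    V = np.exp(-0.05 * t) + rng.normal(0, 0.002, t.size)
    V /= V[0]
    trace = DeerTrace(t, V, np.full_like(t, 0.002))
    path = tmp_path / "trace.txt"
    write_trace(trace, path, "test trace")
    back = read_trace(path)
    assert np.allclose(back.t, trace.t)
    assert np.allclose(back.V, trace.V)
    assert np.allclose(back.sigma, trace.sigma)
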