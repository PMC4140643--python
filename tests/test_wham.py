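"""WHAM density-of-states estimation and derived thermal observables."""

import numpy as np
import pytest
from scipy.special import logsumexp

import bindscape as bs
from bindscape.errors import ConnectivityError, NoPeakError
from bindscape.wham import DensityOfStates, ThermalCurve


def _two_level_dos(e1=5.0, g1=100.0):
    """Ground state (degeneracy 1) at 0, excited level g1 states at e1."""
    edges = np.array([-1.0, 1.0, e1 - 1.0, e1 + 1.0])
    log_n = np.array([0.0, -np.inf, np.log(g1)])
    return DensityOfStates(edges, log_n)


def _schottky_cv(T, e1=5.0, g1=100.0):
    b = 1.0 / T
    z = 1.0 + g1 * np.exp(-b * e1)
    e = e1 * g1 * np.exp(-b * e1) / z
    e2 = e1**2 * g1 * np.exp(-b * e1) / z
    return (e2 - e**2) / T**2


class TestSolveWham:
    def test_recovers_two_level_system_from_exact_histograms(self):
        # expected (infinite-sample) histograms at three temperatures
        edges = np.array([-1.0, 1.0, 4.0, 6.0])
        centers = np.array([0.0, 2.5, 5.0])
        true_log_n = np.array([0.0, -np.inf, np.log(100.0)])
        ladder = np.array([0.5, 1.0, 2.0])
        hist = np.zeros((3, 3))
        for t, T in enumerate(ladder):
            w = np.where(np.isfinite(true_log_n),
                         np.exp(true_log_n - centers / T), 0.0)
            hist[t] = 1e6 * w / w.sum()
        dos = bs.solve_wham(hist, ladder, edges, tol=1e-12)
        ratio = dos.log_n[2] - dos.log_n[0]
        assert ratio == pytest.approx(np.log(100.0), abs=1e-6)

    def test_single_temperature_single_bin_is_anchored(self):
        hist = np.array([[0.0, 50.0, 0.0]])
        dos = bs.solve_wham(hist, [1.0], np.array([0.0, 1, 2, 3.0]))
        assert dos.log_n[1] == pytest.approx(0.0)
        assert np.isneginf(dos.log_n[0]) and np.isneginf(dos.log_n[2])

    def test_disconnected_histograms_raise(self):
        hist = np.array([[10.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
        with pytest.raises(ConnectivityError):
            bs.solve_wham(hist, [0.5, 2.0], np.array([0.0, 1, 2, 3.0]))

    def test_recovers_synthetic_dos_from_samples(self):
        # draws from a known discrete DoS at five temperatures; the
        # recovered log-counts must match on well-sampled bins
        target = (15.0, 5.0, np.log(200.0))
        dos_true = bs.make_discrete_dos(target)
        ladder = np.array([2.0, 3.0, 4.5, 7.0, 10.0])
        edges = dos_true.energy_edges
        hist = np.stack([
            np.histogram(bs.sample_energies(dos_true, T, 100000, seed=10 + i),
                         bins=edges)[0]
            for i, T in enumerate(ladder)]).astype(float)
        dos = bs.solve_wham(hist, ladder, edges)
        well = hist.sum(axis=0) >= 100
        err = dos.log_n[well] - dos_true.log_n[well]
        err = err - err.mean()  # gauge freedom
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_reweighting_consistency(self):
        # canonical <E> from the WHAM DoS matches the direct sample mean
        dos_true = bs.make_discrete_dos((10.0, 3.0, np.log(500.0)))
        ladder = np.array([2.0, 4.0, 8.0])
        samples = [bs.sample_energies(dos_true, T, 50000, seed=3 + i)
                   for i, T in enumerate(ladder)]
        edges = dos_true.energy_edges
        hist = np.stack([np.histogram(s, bins=edges)[0]
                         for s in samples]).astype(float)
        dos = bs.solve_wham(hist, ladder, edges)
        centers = dos.energy_centers
        for T, s in zip(ladder, samples):
            w = dos.log_n - centers / T
            finite = np.isfinite(w)
            p = np.exp(w[finite] - logsumexp(w[finite]))
            e_wham = np.sum(p * centers[finite])
            se = s.std(ddof=1) / np.sqrt(len(s))
            assert abs(e_wham - s.mean()) < 4 * se


class TestHeatCapacity:
    def test_single_level_has_zero_cv(self):
        dos = DensityOfStates(np.array([0.0, 1.0]), np.array([3.0]))
        cv = bs.heat_capacity(dos, np.linspace(0.2, 3, 50))
        assert np.all(cv.y == 0.0)

    def test_two_level_matches_schottky_closed_form(self):
        dos = _two_level_dos()
        T = np.linspace(0.3, 5.0, 200)
        cv = bs.heat_capacity(dos, T)
        # bin centers sit exactly on the levels, so the match is exact
        assert np.abs(cv.y - _schottky_cv(T)).max() < 1e-10

    def test_power_law_dos_gives_constant_cv(self):
        # n(E) ~ E^2 is a Gamma(3) canonical energy distribution: Cv = 3
        edges = np.linspace(0.0, 400.0, 40001)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dos = DensityOfStates(edges, 2.0 * np.log(centers))
        cv = bs.heat_capacity(dos, np.linspace(2.0, 8.0, 7))
        assert np.abs(cv.y - 3.0).max() < 0.01 * 3.0

    def test_gauge_invariance(self):
        dos = _two_level_dos()
        T = np.linspace(0.3, 5.0, 100)
        cv1 = bs.heat_capacity(dos, T)
        cv2 = bs.heat_capacity(dos.shifted(123.4), T)
        np.testing.assert_allclose(cv1.y, cv2.y, rtol=1e-12)

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            bs.heat_capacity(_two_level_dos(), [0.0, 1.0])


class TestFreeEnergyProfile:
    def _dos2d(self, log_n, q=None):
        n_e, n_q = log_n.shape
        edges = np.linspace(-1.0, 1.0 + n_e, n_e + 1)
        q = np.linspace(0, 1, n_q) if q is None else q
        return DensityOfStates(edges, log_n, q)

    def test_flat_landscape(self):
        log_n = np.tile(np.array([[0.0], [1.0], [0.5]]), (1, 4))
        F = bs.free_energy_profile(self._dos2d(log_n), T=1.0)
        assert np.ptp(F.y) < 1e-10

    def test_barrier_height_equals_direct_evaluation(self):
        rng = np.random.default_rng(5)
        log_n = rng.uniform(0, 3, size=(6, 5))
        log_n[:, 2] -= 4.0  # designed barrier at the middle Q column
        dos = self._dos2d(log_n)
        T = 0.7
        F = bs.free_energy_profile(dos, T)
        centers = dos.energy_centers
        direct = np.array([
            -T * logsumexp(log_n[:, j] - centers / T) for j in range(5)])
        direct -= direct.min()
        np.testing.assert_allclose(F.y, direct, atol=1e-12)
        assert np.argmax(F.y) == 2

    def test_high_temperature_limit_is_entropy_dominated(self):
        rng = np.random.default_rng(8)
        log_n = rng.uniform(0, 2, size=(4, 3))
        dos = self._dos2d(log_n)
        T = 1e6
        F = bs.free_energy_profile(dos, T)
        expected = -T * logsumexp(log_n, axis=0)
        expected -= expected.min()
        np.testing.assert_allclose(F.y, expected, rtol=1e-3, atol=1e-2)

    def test_empty_q_column_is_masked(self):
        log_n = np.array([[0.0, -np.inf], [1.0, -np.inf]])
        F = bs.free_energy_profile(self._dos2d(log_n), T=1.0)
        assert np.isnan(F.y[1]) and np.isfinite(F.y[0])


class TestTransitionTemperature:
    def test_schottky_peak_matches_dense_scan(self):
        dos = _two_level_dos()
        grid = np.linspace(0.3, 5.0, 800)
        peak = bs.transition_temperature(bs.heat_capacity(dos, grid))
        dense = np.linspace(0.3, 5.0, 400000)
        t_scan = dense[np.argmax(_schottky_cv(dense))]
        assert peak.temperature == pytest.approx(t_scan, abs=2 * (grid[1] - grid[0]))
        assert peak.width > 0

    def test_flat_curve_has_no_peak(self):
        curve = ThermalCurve(np.linspace(1, 2, 50), np.full(50, 3.0))
        with pytest.raises(NoPeakError):
            bs.transition_temperature(curve)

    def test_monotone_curve_has_no_peak(self):
        x = np.linspace(0.1, 2, 50)
        with pytest.raises(NoPeakError):
            bs.transition_temperature(ThermalCurve(x, x**2))

    def test_symmetric_peak_located_exactly(self):
        x = np.linspace(0.5, 1.5, 101)  # grid point exactly at 1.0
        y = np.exp(-((x - 1.0) / 0.1) ** 2)
        peak = bs.transition_temperature(ThermalCurve(x, y))
        assert peak.temperature == pytest.approx(1.0, abs=1e-12)
        assert not peak.ambiguous

    def test_twin_peaks_flagged_ambiguous(self):
        x = np.linspace(0, 1, 201)
        y = (np.exp(-((x - 0.3) / 0.05) ** 2)
             + 0.995 * np.exp(-((x - 0.7) / 0.05) ** 2))
        peak = bs.transition_temperature(ThermalCurve(x, y))
        assert peak.ambiguous
        assert peak.temperature == pytest.approx(0.3, abs=0.01)


def test_marginal_energy_sums_q_axis():
    log_n = np.log(np.array([[1.0, 2.0], [3.0, 4.0]]))
    dos = DensityOfStates(np.array([0.0, 1, 2]), log_n, np.array([0.0, 1.0]))
    m = dos.marginal_energy()
    np.testing.assert_allclose(np.exp(m.log_n), [3.0, 7.0], rtol=1e-12)
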