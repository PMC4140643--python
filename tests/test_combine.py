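"""Combined binding-folding landscapes: convolution and closed forms."""

import numpy as np
import pytest

import bindscape as bs
from bindscape.combine import BinningError
from bindscape.errors import MeasureError
from bindscape.wham import DensityOfStates


def _random_dos(rng, n_bins=10, start=-5.0, width=1.0, p_empty=0.2):
    log_n = rng.uniform(0, 4, size=n_bins)
    log_n[rng.uniform(size=n_bins) < p_empty] = -np.inf
    if not np.any(np.isfinite(log_n)):
        log_n[0] = 1.0
    edges = start + width * np.arange(n_bins + 1)
    return DensityOfStates(edges, log_n)


def _brute_force_double_convolution(dos_b, dos_f):
    cb = np.exp(dos_b.log_n)
    cf = np.exp(dos_f.log_n)
    nb, nf = len(cb), len(cf)
    out = np.zeros(nb + 2 * (nf - 1))
    for i in range(nb):
        for j in range(nf):
            for k in range(nf):
                out[i + j + k] += cb[i] * cf[j] * cf[k]
    return out


class TestConvolveDos:
    def test_delta_folding_dos_is_identity(self):
        rng = np.random.default_rng(0)
        dos_b = _random_dos(rng)
        dos_f = DensityOfStates(np.array([-0.5, 0.5]), np.array([0.0]))
        comb = bs.convolve_dos(dos_b, dos_f)
        np.testing.assert_allclose(np.exp(comb.log_n), np.exp(dos_b.log_n),
                                   rtol=1e-12)
        np.testing.assert_allclose(
            comb.energy_centers, dos_b.energy_centers, atol=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        dos_b = _random_dos(rng, 10, start=-3.0)
        dos_f = _random_dos(rng, 10, start=-8.0)
        comb = bs.convolve_dos(dos_b, dos_f)
        expected = _brute_force_double_convolution(dos_b, dos_f)
        np.testing.assert_allclose(np.exp(comb.log_n), expected, rtol=1e-10)

    def test_means_add(self):
        rng = np.random.default_rng(2)
        dos_b = _random_dos(rng, 12)
        dos_f = _random_dos(rng, 7, start=-2.0)

        def mean_e(dos):
            w = np.exp(dos.log_n - np.nanmax(dos.log_n[np.isfinite(dos.log_n)]))
            w = np.where(np.isfinite(dos.log_n), w, 0.0)
            return np.sum(w * dos.energy_centers) / w.sum()

        comb = bs.convolve_dos(dos_b, dos_f)
        assert mean_e(comb) == pytest.approx(mean_e(dos_b) + 2 * mean_e(dos_f),
                                             rel=1e-10)

    def test_total_count_multiplies(self):
        rng = np.random.default_rng(3)
        dos_b = _random_dos(rng, 8, p_empty=0.0)
        dos_f = _random_dos(rng, 6, p_empty=0.0)
        comb = bs.convolve_dos(dos_b, dos_f)
        om_b = np.exp(dos_b.log_n).sum()
        om_f = np.exp(dos_f.log_n).sum()
        assert np.exp(comb.log_n).sum() == pytest.approx(om_b * om_f**2,
                                                         rel=1e-10)

    def test_commutes_and_associates(self):
        rng = np.random.default_rng(4)
        a = np.exp(_random_dos(rng, 6, p_empty=0.0).log_n)
        b = np.exp(_random_dos(rng, 9, p_empty=0.0).log_n)
        c = np.exp(_random_dos(rng, 5, p_empty=0.0).log_n)
        np.testing.assert_allclose(np.convolve(a, b), np.convolve(b, a),
                                   rtol=1e-12)
        np.testing.assert_allclose(
            np.convolve(np.convolve(a, b), c),
            np.convolve(a, np.convolve(b, c)), rtol=1e-12)

    def test_incompatible_widths_need_resampling(self):
        dos_b = DensityOfStates(np.array([0.0, 1.0, 2.0]), np.zeros(2))
        dos_f = DensityOfStates(np.array([0.0, 0.3, 0.6]), np.zeros(2))
        with pytest.raises(BinningError):
            bs.convolve_dos(dos_b, dos_f, resample=False)
        comb = bs.convolve_dos(dos_b, dos_f, resample=True)
        # counts are conserved by the rebinning
        assert np.exp(comb.log_n).sum() == pytest.approx(2.0 * 4.0, rel=1e-9)


class TestCombineTopography:
    def _topo(self, dE, DE, S, label="x", conv="native"):
        lam = bs.lambda_measure(dE, DE, S) if DE > 0 and S > 0 else 0.0
        tg = bs.glass_temperature(DE, S) if S > 0 else 1.0
        return bs.LandscapeTopography(delta_E=dE, Delta_E=DE, S=S, Lambda=lam,
                                      Tf=1.0, Tg=tg, Tf_over_Tg=1.0 / tg,
                                      label=label, convention=conv)

    def test_rigid_folded_limit_reduces_to_binding(self):
        b = self._topo(50.0, 10.0, 40.0)
        f = self._topo(0.0, 0.0, 0.0)
        comb = bs.combine_topography(b, f)
        assert comb.delta_E == b.delta_E
        assert comb.Delta_E == b.Delta_E
        assert comb.S == b.S
        assert comb.Lambda == pytest.approx(b.Lambda, rel=1e-12)

    def test_closed_forms_match_convolution_moments(self):
        # convolve the non-native parts of two exact-moment DoS and check
        # gap additivity, variance in quadrature and entropy additivity
        tb, tf = (20.0, 4.0, np.log(300.0)), (60.0, 7.0, np.log(1000.0))
        dos_b, dos_f = bs.make_discrete_dos(tb), bs.make_discrete_dos(tf)

        def nn_counts(dos):
            occ = np.flatnonzero(np.isfinite(dos.log_n))
            e = dos.energy_centers[occ[1:]]
            c = np.exp(dos.log_n[occ[1:]])
            return e, c

        eb, cb = nn_counts(dos_b)
        ef, cf = nn_counts(dos_f)
        es, cs = [], []
        for i, x in enumerate(eb):
            for j, y in enumerate(ef):
                for k, z in enumerate(ef):
                    es.append(x + y + z)
                    cs.append(cb[i] * cf[j] * cf[k])
        es, cs = np.array(es), np.array(cs)
        mean = np.sum(cs * es) / cs.sum()
        var = np.sum(cs * es**2) / cs.sum() - mean**2
        comb = bs.combine_topography(self._topo(*tb), self._topo(*tf))
        assert comb.delta_E == pytest.approx(mean, rel=1e-12)
        assert comb.Delta_E == pytest.approx(np.sqrt(var), rel=1e-12)
        assert comb.S == pytest.approx(np.log(cs.sum()), rel=1e-12)

    def test_lambda_is_definitionally_consistent(self):
        comb = bs.combine_topography(self._topo(50.0, 10.0, 40.0),
                                     self._topo(200.0, 9.0, 190.0))
        assert comb.Lambda == pytest.approx(
            bs.lambda_measure(comb.delta_E, comb.Delta_E, comb.S), rel=1e-14)

    def test_entropy_additivity_is_exact(self):
        b = self._topo(50.0, 10.0, 42.12)
        f = self._topo(200.0, 9.0, 189.35)
        comb = bs.combine_topography(b, f)
        assert comb.S == b.S + 2 * f.S

    def test_convention_mismatch_rejected(self):
        with pytest.raises(MeasureError):
            bs.combine_topography(self._topo(1, 1, 1.0),
                                  self._topo(1, 1, 1.0, conv="raw"))


class TestCombinedGlobalGap:
    def test_equal_lambdas_give_zero(self):
        assert bs.combined_global_gap(1.3, 1.3) == 0.0

    def test_definition(self):
        assert bs.combined_global_gap(1.0, 2.0) == pytest.approx(0.5)

    def test_non_positive_lambda_rejected(self):
        with pytest.raises(MeasureError):
            bs.combined_global_gap(0.0, 1.0)
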