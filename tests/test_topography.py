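"""Landscape topography: partition, moments, Tg, Lambda, published tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bindscape as bs
from bindscape import reference
from bindscape.errors import MeasureError, PartitionError
from bindscape.wham import DensityOfStates


def _dos_three_strata():
    """(E, Q) DoS with native mass in the maximal-Q stratum."""
    edges = np.array([-10.0, -5.0, 0.0, 5.0])
    q = np.array([0.0, 0.5, 1.0])
    log_n = np.full((3, 3), -np.inf)
    log_n[0, 2] = 0.0          # native: low E, Q = 1
    log_n[1, 1] = np.log(50.0)
    log_n[2, 0] = np.log(200.0)
    log_n[2, 1] = np.log(30.0)
    return DensityOfStates(edges, log_n, q)


class TestPartitionStates:
    def test_unique_native_bin_in_max_q_stratum(self):
        dos = _dos_three_strata()
        part = bs.partition_states(dos, "max_q")
        assert part.native.sum() == 1
        assert part.native[0, 2]
        assert part.non_native.sum() == 3

    def test_max_q_stratum_found_by_enumeration(self):
        dos = _dos_three_strata()
        part = bs.partition_states(dos, "max_q")
        occ = np.isfinite(dos.log_n)
        q_max = max(dos.q_values[j] for i, j in zip(*np.where(occ)))
        for i, j in zip(*np.where(occ)):
            assert part.native[i, j] == (dos.q_values[j] == q_max)

    def test_min_energy_fallback_for_1d_dos(self):
        dos = bs.make_discrete_dos((10.0, 2.0, np.log(100.0)))
        part = bs.partition_states(dos, "min_energy")
        lowest = np.flatnonzero(np.isfinite(dos.log_n))[0]
        assert part.native[lowest]
        assert part.native.sum() == 1

    def test_all_native_is_partition_error(self):
        dos = DensityOfStates(np.array([0.0, 1.0]), np.array([0.0]))
        with pytest.raises(PartitionError):
            bs.partition_states(dos, "min_energy")

    def test_q_threshold_rule(self):
        dos = _dos_three_strata()
        part = bs.partition_states(dos, "max_q", q_native=0.5)
        assert part.native.sum() == 3  # Q in {0.5, 1.0} strata


class TestLandscapeMoments:
    def test_brute_force_two_level_example(self):
        # native: one state at 0; non-native: 100 states at 10, 100 at 20
        dos = bs.make_discrete_dos((15.0, 5.0, np.log(200.0)))
        part = bs.partition_states(dos, "min_energy")
        dE, DE, S = bs.landscape_moments(dos, part)
        # brute force over the 201 explicit states
        energies = np.array([10.0] * 100 + [20.0] * 100)
        assert dE == pytest.approx(energies.mean() - 0.0, rel=1e-12)
        assert DE == pytest.approx(energies.std(), rel=1e-12)
        assert S == pytest.approx(np.log(200.0), rel=1e-12)

    def test_degenerate_non_native_level_has_zero_roughness(self):
        dos = bs.make_discrete_dos((7.0, 0.0, np.log(40.0)))
        part = bs.partition_states(dos, "min_energy")
        dE, DE, S = bs.landscape_moments(dos, part)
        assert DE == 0.0
        assert dE == pytest.approx(7.0)

    @settings(deadline=None, max_examples=30)
    @given(dE=st.floats(2.0, 500.0), ratio=st.floats(0.01, 0.9),
           S=st.floats(0.5, 300.0))
    def test_round_trip_with_generator(self, dE, ratio, S):
        DE = ratio * dE
        dos = bs.make_discrete_dos((dE, DE, S))
        part = bs.partition_states(dos, "min_energy")
        got = bs.landscape_moments(dos, part)
        assert got[0] == pytest.approx(dE, rel=1e-9)
        assert got[1] == pytest.approx(DE, rel=1e-9, abs=1e-9)
        assert got[2] == pytest.approx(S, rel=1e-9)

    def test_energy_rescaling_covariance(self):
        # E -> cE scales gap, roughness, Tg by c; S and Lambda unchanged
        dos = bs.make_discrete_dos((12.0, 3.0, np.log(150.0)))
        c = 2.5
        scaled = DensityOfStates(dos.energy_edges * c, dos.log_n)
        for d, scale in ((dos, 1.0), (scaled, c)):
            part = bs.partition_states(d, "min_energy")
            dE, DE, S = bs.landscape_moments(d, part)
            assert dE == pytest.approx(12.0 * scale, rel=1e-12)
            assert DE == pytest.approx(3.0 * scale, rel=1e-12)
            assert S == pytest.approx(np.log(150.0), rel=1e-12)
            assert bs.lambda_measure(dE, DE, S) == pytest.approx(
                bs.lambda_measure(12.0, 3.0, np.log(150.0)), rel=1e-12)
            assert bs.glass_temperature(DE, S) == pytest.approx(
                scale * bs.glass_temperature(3.0, np.log(150.0)), rel=1e-12)


class TestClosedForms:
    @pytest.mark.parametrize("DE,S,expected", [
        (11.01, 42.12, 1.20),   # rigid binding, Cro repressor dimer
        (5.77, 64.00, 0.51),    # flexible binding, lambda repressor
        (1.0, 0.5, 1.0),
    ])
    def test_glass_temperature(self, DE, S, expected):
        assert bs.glass_temperature(DE, S) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("dE,DE,S,expected", [
        (57.56, 11.01, 42.12, 0.56),    # rigid binding, Cro repressor
        (205.95, 9.34, 189.35, 1.13),   # isolated folding, Cro monomer
    ])
    def test_lambda_measure(self, dE, DE, S, expected):
        assert bs.lambda_measure(dE, DE, S) == pytest.approx(expected,
                                                             abs=0.02)

    def test_gapless_landscape_has_zero_lambda(self):
        assert bs.lambda_measure(0.0, 3.0, 10.0) == 0.0

    def test_zero_roughness_lambda_undefined(self):
        with pytest.raises(MeasureError):
            bs.lambda_measure(5.0, 0.0, 10.0)

    def test_non_positive_entropy_rejected(self):
        with pytest.raises(MeasureError):
            bs.glass_temperature(3.0, 0.0)
        with pytest.raises(MeasureError):
            bs.lambda_measure(5.0, 1.0, -1.0)

    def test_lambda_tg_identity(self):
        # Lambda = dE * Tg / DE^2 to machine precision
        rng = np.random.default_rng(2)
        for _ in range(20):
            dE = rng.uniform(1, 300)
            DE = rng.uniform(0.1, 20)
            S = rng.uniform(1, 400)
            lam = bs.lambda_measure(dE, DE, S)
            tg = bs.glass_temperature(DE, S)
            assert lam == pytest.approx(dE * tg / DE**2, rel=1e-12)

    @pytest.mark.parametrize("tf,tg,expected", [
        (1.95, 1.20, 1.62), (1.24, 0.55, 2.25)])
    def test_tf_over_tg(self, tf, tg, expected):
        assert tf / tg == pytest.approx(expected, abs=0.01)


class TestPublishedTableConsistency:
    """Lambda, Tg and Tf/Tg recomputed from every published gap/roughness/
    entropy column must agree with the published values (rounding of the
    printed inputs allows +/-0.02)."""

    @pytest.mark.parametrize("table", [reference.BINDING, reference.FOLDING])
    def test_all_columns(self, table):
        for pdb, cols in table.items():
            for mode, row in cols.items():
                tg = bs.glass_temperature(row["Delta_E"], row["S"])
                lam = bs.lambda_measure(row["delta_E"], row["Delta_E"],
                                        row["S"])
                assert tg == pytest.approx(row["Tg"], abs=0.02), (pdb, mode)
                assert lam == pytest.approx(row["Lambda"], abs=0.02), (pdb, mode)
                assert row["Tf"] / tg == pytest.approx(row["Tf_over_Tg"],
                                                       abs=0.02), (pdb, mode)


class TestTopographySummary:
    def test_assembles_consistent_measures(self):
        dos = _dos_three_strata()
        topo = bs.topography_summary(dos, T_grid=np.linspace(0.5, 30, 2000),
                                     label="binding")
        dE, DE, S = bs.landscape_moments(dos,
                                         bs.partition_states(dos, "max_q"))
        assert topo.delta_E == pytest.approx(dE)
        assert topo.Lambda == pytest.approx(bs.lambda_measure(dE, DE, S))
        assert topo.Tf_over_Tg == pytest.approx(topo.Tf / topo.Tg)
        assert topo.label == "binding"

    def test_invalid_measures_rejected(self):
        with pytest.raises(MeasureError):
            bs.LandscapeTopography(delta_E=1.0, Delta_E=-0.1, S=1.0,
                                   Lambda=0.1, Tf=1.0, Tg=1.0,
                                   Tf_over_Tg=1.0)
        with pytest.raises(MeasureError):
            bs.LandscapeTopography(delta_E=1.0, Delta_E=1.0, S=1.0,
                                   Lambda=0.1, Tf=1.0, Tg=-1.0,
                                   Tf_over_Tg=1.0)
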