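"""Energy-landscape topography: gap, roughness, entropy, Tg and Lambda.

The density of states is split into a native macrostate and the non-native
remainder.  With count-weighted statistics over non-native bins:

* gap        dE = <E>_nn - E_native          (slope toward the native state)
* roughness  DE = std(E)_nn                  (bumpiness of the landscape)
* entropy    S  = ln(Omega_nn / Omega_native)  (size of the search space)

Random-energy-model statistics give the glass-trapping temperature
Tg = DE / sqrt(2 S), and the dimensionless topography measure

    Lambda = dE / (DE sqrt(2 S))

is the thermodynamic intrinsic specificity: gap against roughness,
modulated by entropy.  Larger Lambda means a more funneled landscape.
All ratios are invariant under the WHAM normalization constant; we adopt
the native gauge (Omega_native = 1) so entropies are pure landscape-shape
quantities on the scale of tens, and so state counts multiply correctly
when landscapes are composed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MeasureError, PartitionError
from .wham import (DensityOfStates, ThermalCurve, heat_capacity,
                   transition_temperature)


@dataclass(frozen=True)
class Partition:
    """Boolean masks over DoS bins: native macrostate vs the rest."""

    native: np.ndarray
    non_native: np.ndarray

    def __post_init__(self):
        if not self.native.any():
            raise PartitionError("native set is empty")
        if not self.non_native.any():
            raise PartitionError("non-native set is empty")
        if (self.native & self.non_native).any():
            raise PartitionError("native and non-native sets overlap")


@dataclass(frozen=True)
class LandscapeTopography:
    """Topography summary of one landscape (binding, folding or global)."""

    delta_E: float
    Delta_E: float
    S: float
    Lambda: float
    Tf: float
    Tg: float
    Tf_over_Tg: float
    label: str = ""
    Tf_width: float = float("nan")
    convention: str = "native"

    def __post_init__(self):
        if self.Delta_E < 0:
            raise MeasureError("roughness must be non-negative")
        if self.S < 0:
            raise MeasureError("entropy must be non-negative")
        if self.Lambda < 0:
            raise MeasureError("Lambda must be non-negative")
        if self.Delta_E > 0 and self.S > 0 and not self.Tg > 0:
            raise MeasureError("Tg must be positive for a rough landscape")


def partition_states(dos: DensityOfStates, native_rule: str = "max_q",
                     q_native: float | None = None,
                     q_floor: float | None = None) -> Partition:
    """Split DoS bins into native and non-native sets.

    ``max_q`` (default, needs a Q axis): native bins are those at the
    maximal occupied Q stratum, or the basin Q >= ``q_native`` when given.
    ``min_energy``: native is the lowest occupied energy bin (fallback for
    a DoS without a Q axis).

    ``q_floor``, when given, drops bins with Q <= q_floor from the
    non-native set: states with no native contact at all belong to the
    dissociated/denatured continuum, whose weight reflects the confinement
    volume rather than landscape topography.
    """
    occ = np.isfinite(dos.log_n)
    if native_rule == "max_q":
        if not dos.is_2d:
            raise PartitionError("max_q rule needs a DoS with a Q axis")
        occ_q = occ.any(axis=0)
        thresh = q_native if q_native is not None else dos.q_values[occ_q].max()
        native = occ & (dos.q_values[None, :] >= thresh - 1e-12)
        if q_floor is not None:
            return Partition(
                native=native,
                non_native=occ & ~native
                & (dos.q_values[None, :] > q_floor + 1e-12))
    elif native_rule == "min_energy":
        ln = dos.log_n if not dos.is_2d else dos.log_n
        occ_e = occ if ln.ndim == 1 else occ.any(axis=1)
        lowest = np.flatnonzero(occ_e)[0]
        native = np.zeros_like(occ)
        if ln.ndim == 1:
            native[lowest] = occ[lowest]
        else:
            native[lowest, :] = occ[lowest, :]
    else:
        raise ValueError(f"unknown native rule {native_rule!r}")
    return Partition(native=native, non_native=occ & ~native)


def _masked_stats(dos: DensityOfStates, mask: np.ndarray):
    """(log Omega, <E>, <E^2>) over masked bins, log-domain safe."""
    ln = dos.log_n[mask]
    if dos.is_2d:
        E = np.broadcast_to(dos.energy_centers[:, None], dos.log_n.shape)[mask]
    else:
        E = dos.energy_centers[mask]
    a = ln.max()
    w = np.exp(ln - a)
    W = w.sum()
    log_omega = a + np.log(W)
    e1 = float(np.sum(w * E) / W)
    e2 = float(np.sum(w * E**2) / W)
    return log_omega, e1, e2


def landscape_moments(dos: DensityOfStates, partition: Partition):
    """(delta_E, Delta_E, S) of a partitioned density of states."""
    log_om_nat, e_nat, _ = _masked_stats(dos, partition.native)
    log_om_nn, e1, e2 = _masked_stats(dos, partition.non_native)
    delta_E = e1 - e_nat
    Delta_E = float(np.sqrt(max(e2 - e1 * e1, 0.0)))
    S = float(log_om_nn - log_om_nat)
    return delta_E, Delta_E, S


def native_gauge(dos: DensityOfStates, partition: Partition) -> DensityOfStates:
    """Shift log-counts so the native macrostate holds exactly one state."""
    log_om_nat, _, _ = _masked_stats(dos, partition.native)
    return dos.shifted(-log_om_nat, normalization="native")


def glass_temperature(Delta_E: float, S: float) -> float:
    """Tg = Delta_E / sqrt(2 S) (random-energy-model trapping temperature)."""
    if S <= 0:
        raise MeasureError("Tg undefined for non-positive entropy")
    if Delta_E < 0:
        raise MeasureError("roughness must be non-negative")
    return Delta_E / np.sqrt(2.0 * S)


def lambda_measure(delta_E: float, Delta_E: float, S: float) -> float:
    """Lambda = delta_E / (Delta_E sqrt(2 S)), the intrinsic specificity."""
    if S <= 0:
        raise MeasureError("Lambda undefined for non-positive entropy")
    if Delta_E == 0:
        raise MeasureError("Lambda undefined for zero roughness")
    if delta_E == 0:
        return 0.0
    return delta_E / (Delta_E * np.sqrt(2.0 * S))


def topography_summary(dos: DensityOfStates, cv_curve: ThermalCurve | None = None,
                       *, T_grid=None, native_rule: str = "max_q",
                       q_native: float | None = None,
                       q_floor: float | None = None,
                       label: str = "") -> LandscapeTopography:
    """Assemble delta_E, Delta_E, S, Lambda, Tf, Tg and Tf/Tg for one DoS."""
    part = partition_states(dos, native_rule, q_native, q_floor)
    delta_E, Delta_E, S = landscape_moments(dos, part)
    if cv_curve is None:
        if T_grid is None:
            T_grid = np.linspace(0.2, 2.2, 2001)
        cv_curve = heat_capacity(dos, T_grid)
    peak = transition_temperature(cv_curve)
    Tg = glass_temperature(Delta_E, S)
    Lam = lambda_measure(delta_E, Delta_E, S)
    return LandscapeTopography(
        delta_E=float(delta_E), Delta_E=float(Delta_E), S=float(S),
        Lambda=float(Lam), Tf=peak.temperature, Tg=float(Tg),
        Tf_over_Tg=peak.temperature / Tg, label=label,
        Tf_width=peak.width)
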