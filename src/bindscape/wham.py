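"""Weighted histogram analysis: canonical samples -> density of states.

Multi-temperature histograms over (E[, Q]) bins are combined into the
micro-canonical density of states n(E[, Q]) by the self-consistent WHAM
equations, iterated in the log domain:

    ln n_k = ln(sum_t H_tk) - ln(sum_t N_t exp(f_t - E_k / T_t))
    f_t    = -ln(sum_k n_k exp(-E_k / T_t))

The density of states is the "intrinsic energy landscape" from which every
canonical observable derives: heat capacity Cv(T), free-energy profiles
F(Q; T) and transition temperatures at the Cv peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .errors import ConnectivityError, ConvergenceError, NoPeakError


@dataclass(frozen=True)
class DensityOfStates:
    """Log-counts over energy (and optionally Q) bins.

    ``log_n`` is shaped (nE,) or (nE, nQ); unoccupied bins hold -inf.
    ``normalization`` records the gauge: ``"raw"`` (arbitrary additive
    constant) or ``"native"`` (native macrostate count = 1).
    """

    energy_edges: np.ndarray
    log_n: np.ndarray
    q_values: np.ndarray | None = None
    normalization: str = "raw"

    def __post_init__(self):
        edges = np.asarray(self.energy_edges, dtype=float)
        object.__setattr__(self, "energy_edges", edges)
        object.__setattr__(self, "log_n", np.asarray(self.log_n, dtype=float))
        if self.q_values is not None:
            object.__setattr__(self, "q_values",
                               np.asarray(self.q_values, dtype=float))
        if not np.all(np.diff(edges) > 0):
            raise ValueError("energy bin edges must be strictly increasing")
        want = (len(edges) - 1,) if self.q_values is None else \
            (len(edges) - 1, len(self.q_values))
        if self.log_n.shape != want:
            raise ValueError(f"log_n shape {self.log_n.shape}, expected {want}")
        occ = self.log_n[np.isfinite(self.log_n)]
        if occ.size == 0:
            raise ValueError("density of states has no occupied bin")

    @property
    def is_2d(self) -> bool:
        return self.q_values is not None

    @property
    def energy_centers(self) -> np.ndarray:
        return 0.5 * (self.energy_edges[:-1] + self.energy_edges[1:])

    def marginal_energy(self) -> "DensityOfStates":
        """Sum out the Q axis (log-domain)."""
        if not self.is_2d:
            return self
        with np.errstate(divide="ignore"):
            ln = logsumexp(self.log_n, axis=1)
        return DensityOfStates(self.energy_edges, ln, None, self.normalization)

    def shifted(self, delta: float, normalization: str | None = None
                ) -> "DensityOfStates":
        return replace(self, log_n=self.log_n + delta,
                       normalization=normalization or self.normalization)


@dataclass(frozen=True)
class ThermalCurve:
    """A curve over temperature (Cv) or over Q (free-energy profile)."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""
    kind: str = "Cv"

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if len(self.x) != len(self.y):
            raise ValueError("x and y lengths differ")
        if len(self.x) > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("grid must be strictly increasing")


@dataclass(frozen=True)
class TransitionPoint:
    """Heat-capacity peak: location, half-height width, ambiguity flag."""

    temperature: float
    width: float
    ambiguous: bool = False


def solve_wham(histograms: np.ndarray, ladder, energy_edges,
               q_values=None, *, tol: float = 1e-7, max_iter: int = 100000,
               damping: float = 0.5) -> DensityOfStates:
    """Self-consistent density of states from per-temperature histograms.

    ``histograms`` is (nT, nE) or (nT, nE, nQ); counts need not be integer.
    Convergence is on the maximum change of the per-temperature free-energy
    shifts f_t; the result is fixed to the ``"raw"`` gauge with
    max(log n) = 0.
    """
    hist = np.asarray(histograms, dtype=float)
    ladder = np.atleast_1d(np.asarray(ladder, dtype=float))
    edges = np.asarray(energy_edges, dtype=float)
    if hist.ndim == 2:
        hist = hist[:, :, None]
    n_temps, n_e, n_q = hist.shape
    if len(ladder) != n_temps:
        raise ValueError("ladder length does not match histogram count")
    if np.any(ladder <= 0):
        raise ValueError("temperatures must be positive")

    # neighbouring temperatures must share occupied energy bins
    e_occ = hist.sum(axis=2) > 0
    for t in range(n_temps - 1):
        if not np.any(e_occ[t] & e_occ[t + 1]):
            raise ConnectivityError(
                f"histograms at T={ladder[t]:.4g} and T={ladder[t + 1]:.4g} "
                "share no occupied energy bin")

    centers = 0.5 * (edges[:-1] + edges[1:])
    flat = hist.reshape(n_temps, -1)
    C = flat.sum(axis=0)                      # total counts per bin
    occ = C > 0
    E_k = np.repeat(centers, n_q)[occ]
    ln_C = np.log(C[occ])
    N_t = flat.sum(axis=1)
    ln_N = np.log(np.where(N_t > 0, N_t, 1.0))
    beta = 1.0 / ladder

    f = np.zeros(n_temps)
    bE = beta[:, None] * E_k[None, :]         # (nT, nK)
    for _ in range(max_iter):
        ln_denom = logsumexp(ln_N[:, None] + f[:, None] - bE, axis=0)
        ln_n = ln_C - ln_denom
        f_new = -logsumexp(ln_n[None, :] - bE, axis=1)
        f_new -= f_new[0]
        df = np.max(np.abs(f_new - f))
        f = (1.0 - damping) * f + damping * f_new
        if df < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {df:.3e} > tol {tol:g})")

    ln_denom = logsumexp(ln_N[:, None] + f[:, None] - bE, axis=0)
    ln_n = ln_C - ln_denom
    log_n = np.full(n_e * n_q, -np.inf)
    log_n[occ] = ln_n - ln_n.max()
    log_n = log_n.reshape(n_e, n_q)
    if q_values is None:
        log_n = log_n[:, 0]
    return DensityOfStates(edges, log_n, q_values, normalization="raw")


def _canonical_moments(log_n_e: np.ndarray, centers: np.ndarray, T: float):
    w = log_n_e - centers / T
    finite = np.isfinite(w)
    wf, Ef = w[finite], centers[finite]
    a = wf.max()
    p = np.exp(wf - a)
    Z = p.sum()
    e1 = float(np.sum(p * Ef) / Z)
    e2 = float(np.sum(p * Ef**2) / Z)
    return e1, e2


def heat_capacity(dos: DensityOfStates, T_grid) -> ThermalCurve:
    """Cv(T) = (<E^2> - <E>^2) / T^2 from canonical averages over the DoS."""
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    if np.any(T_grid <= 0):
        raise ValueError("temperatures must be positive")
    mdos = dos.marginal_energy()
    centers = mdos.energy_centers
    cv = np.empty(len(T_grid))
    for i, T in enumerate(T_grid):
        e1, e2 = _canonical_moments(mdos.log_n, centers, T)
        cv[i] = max(e2 - e1 * e1, 0.0) / T**2
    return ThermalCurve(T_grid, cv, kind="Cv")


def free_energy_profile(dos: DensityOfStates, T: float) -> ThermalCurve:
    """F(Q; T) = -T ln sum_E n(E, Q) exp(-E/T), shifted so min F = 0.

    Empty Q columns are masked (NaN), not an error.
    """
    if not dos.is_2d:
        raise ValueError("free-energy profile needs a DoS with a Q axis")
    if T <= 0:
        raise ValueError("temperature must be positive")
    centers = dos.energy_centers
    F = np.full(len(dos.q_values), np.nan)
    for j in range(len(dos.q_values)):
        col = dos.log_n[:, j]
        finite = np.isfinite(col)
        if not np.any(finite):
            continue
        F[j] = -T * logsumexp(col[finite] - centers[finite] / T)
    if np.all(np.isnan(F)):
        raise ValueError("free-energy profile is empty")
    F -= np.nanmin(F)
    return ThermalCurve(dos.q_values, F, kind="F")


def transition_temperature(cv: ThermalCurve) -> TransitionPoint:
    """Locate the Cv peak: interior argmax with 3-point parabolic refinement.

    Returns the peak temperature and its full width at half height.  A
    monotone or flat curve raises ``NoPeakError``; if a second local
    maximum lies within 1% of the peak height the result is flagged
    ambiguous.  Ties break to the lowest temperature.
    """
    T, y = cv.x, cv.y
    if len(T) < 3:
        raise NoPeakError("grid too coarse to bracket a peak")
    interior = np.arange(1, len(T) - 1)
    local = interior[(y[interior] > y[interior - 1]) &
                     (y[interior] >= y[interior + 1])]
    scale = np.max(np.abs(y)) if np.max(np.abs(y)) > 0 else 1.0
    peaks = local[y[local] > max(y[0], y[-1]) + 1e-9 * scale]
    if len(peaks) == 0:
        raise NoPeakError("heat-capacity curve has no interior maximum")
    best = peaks[np.argmax(y[peaks])]
    # lowest-T tie-break and 1% ambiguity flag
    near = peaks[y[peaks] >= y[best] * 0.99]
    ambiguous = len(near) > 1
    i = int(near.min())
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom < 0:
        frac = 0.5 * (y0 - y2) / denom
        frac = np.clip(frac, -0.5, 0.5)
        t_peak = T[i] + frac * (T[min(i + 1, len(T) - 1)] - T[i - 1]) / 2.0
    else:
        t_peak = T[i]
    half = y[i] / 2.0
    lo = np.nan
    for j in range(i, 0, -1):
        if y[j - 1] < half <= y[j]:
            lo = np.interp(half, [y[j - 1], y[j]], [T[j - 1], T[j]])
            break
    hi = np.nan
    for j in range(i, len(T) - 1):
        if y[j + 1] < half <= y[j]:
            hi = np.interp(half, [y[j + 1], y[j]], [T[j + 1], T[j]])
            break
    width = hi - lo if np.isfinite(lo) and np.isfinite(hi) else np.nan
    return TransitionPoint(float(t_peak), float(width), bool(ambiguous))
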