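"""Combined binding-folding landscapes from independent components.

For a homodimer whose binding and folding are weakly coupled, the whole
binding-folding density of states factorizes into one interfacial-binding
landscape and two (identical) monomeric-folding landscapes:

    n_comb(E) = sum_{Eb + Ef1 + Ef2 = E} n_b(Eb) n_f(Ef1) n_f(Ef2)

i.e. a double discrete convolution over energy, under which state counts
multiply (Omega_comb = Omega_b * Omega_f^2).  In the native gauge
(Omega_native = 1 per landscape) the topography of the combined landscape
follows in closed form:

    dE_comb = dE_b + 2 dE_f
    DE_comb = sqrt(DE_b^2 + 2 DE_f^2)
    S_comb  = S_b + 2 S_f
    Lambda_comb = dE_comb / (DE_comb sqrt(2 S_comb))

Comparing Lambda_comb with the Lambda of the directly sampled global
landscape measures how strongly binding and folding are actually coupled:
the relative difference grows with the interfacial flexibility rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BindscapeError, MeasureError
from .topography import LandscapeTopography, lambda_measure
from .wham import DensityOfStates


class BinningError(BindscapeError):
    """Energy grids are incompatible and resampling is disabled."""


@dataclass(frozen=True)
class CombinedTopography:
    """Closed-form topography of a combined binding-folding landscape."""

    delta_E: float
    Delta_E: float
    S: float
    Lambda: float
    binding_label: str = ""
    folding_label: str = ""
    convention: str = "native"

    def __post_init__(self):
        if self.Delta_E < 0 or self.S < 0 or self.Lambda < 0:
            raise MeasureError("combined moments must be non-negative")


def _rebin(dos: DensityOfStates, width: float) -> DensityOfStates:
    """Count-conserving rebin of a 1-D DoS onto a grid of ``width``."""
    edges = dos.energy_edges
    lo, hi = edges[0], edges[-1]
    n_new = int(np.ceil((hi - lo) / width - 1e-12))
    new_edges = lo + width * np.arange(n_new + 1)
    counts = np.zeros(n_new)
    ln = dos.log_n
    finite = np.isfinite(ln)
    a = ln[finite].max()
    for k in np.flatnonzero(finite):
        c = np.exp(ln[k] - a)
        b_lo, b_hi = edges[k], edges[k + 1]
        j0 = max(0, int((b_lo - lo) / width))
        j1 = min(n_new - 1, int((b_hi - lo - 1e-15) / width))
        for j in range(j0, j1 + 1):
            ov = min(b_hi, new_edges[j + 1]) - max(b_lo, new_edges[j])
            if ov > 0:
                counts[j] += c * ov / (b_hi - b_lo)
    with np.errstate(divide="ignore"):
        return DensityOfStates(new_edges, np.log(counts) + a, None,
                               dos.normalization)


def convolve_dos(dos_b: DensityOfStates, dos_f: DensityOfStates, *,
                 resample: bool = True) -> DensityOfStates:
    """Combined DoS: n_b convolved twice with n_f (homodimer).

    Requires 1-D (energy-only) densities on equal bin widths; with
    ``resample`` the folding DoS is rebinned count-conservingly onto the
    binding grid first.
    """
    if dos_b.is_2d or dos_f.is_2d:
        dos_b, dos_f = dos_b.marginal_energy(), dos_f.marginal_energy()
    wb = np.diff(dos_b.energy_edges)
    wf = np.diff(dos_f.energy_edges)
    if (np.ptp(wb) > 1e-9 * wb.mean()) or (np.ptp(wf) > 1e-9 * wf.mean()):
        if not resample:
            raise BinningError("non-uniform energy bins; enable resampling")
        w = wb.min()
        dos_b, dos_f = _rebin(dos_b, w), _rebin(dos_f, w)
        wb, wf = np.diff(dos_b.energy_edges), np.diff(dos_f.energy_edges)
    if abs(wb.mean() - wf.mean()) > 1e-9 * wb.mean():
        if not resample:
            raise BinningError(
                f"bin widths differ ({wb.mean():.4g} vs {wf.mean():.4g}) "
                "and resampling is disabled")
        dos_f = _rebin(dos_f, wb.mean())
        wf = np.diff(dos_f.energy_edges)

    lb, lf = dos_b.log_n, dos_f.log_n
    ab = lb[np.isfinite(lb)].max()
    af = lf[np.isfinite(lf)].max()
    cb = np.exp(np.where(np.isfinite(lb), lb - ab, -np.inf))
    cf = np.exp(np.where(np.isfinite(lf), lf - af, -np.inf))
    conv = np.convolve(np.convolve(cb, cf), cf)
    w = wb.mean()
    # centers add: first combined center = cb0 + 2*cf0, i.e. summed lower
    # edges plus 3w/2, so the combined grid's lower edge sits at +w
    start = dos_b.energy_edges[0] + 2 * dos_f.energy_edges[0] + w
    edges = start + w * np.arange(len(conv) + 1)
    with np.errstate(divide="ignore"):
        log_n = np.log(conv) + ab + 2 * af
    tag = (dos_b.normalization
           if dos_b.normalization == dos_f.normalization else "raw")
    return DensityOfStates(edges, log_n, None, tag)


def combine_topography(topo_b: LandscapeTopography,
                       topo_f: LandscapeTopography) -> CombinedTopography:
    """Closed-form combined topography from binding + 2x folding."""
    if topo_b.convention != topo_f.convention:
        raise MeasureError(
            f"entropy conventions differ: {topo_b.convention!r} vs "
            f"{topo_f.convention!r}")
    dE = topo_b.delta_E + 2.0 * topo_f.delta_E
    DE = float(np.sqrt(topo_b.Delta_E**2 + 2.0 * topo_f.Delta_E**2))
    S = topo_b.S + 2.0 * topo_f.S
    lam = lambda_measure(dE, DE, S) if DE > 0 and S > 0 else 0.0
    return CombinedTopography(delta_E=dE, Delta_E=DE, S=S, Lambda=lam,
                              binding_label=topo_b.label,
                              folding_label=topo_f.label,
                              convention=topo_b.convention)


def combined_global_gap(lambda_comb: float, lambda_glob: float) -> float:
    """Relative topography difference (Lambda_glob - Lambda_comb)/Lambda_glob.

    Positive when the directly sampled global landscape is more funneled
    than the weak-coupling combination; grows with interfacial flexibility.
    """
    if lambda_comb <= 0 or lambda_glob <= 0:
        raise MeasureError("both Lambda values must be positive")
    return (lambda_glob - lambda_comb) / lambda_glob
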