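"""Potential energy, forces and native-contact fractions.

The SBM potential, in reduced units:

* bond            ``k_b (r - r0)^2``
* angle           ``k_a (theta - theta0)^2``
* dihedral        ``k_d1 [1 - cos(phi - phi0)] + k_d3 [1 - cos 3(phi - phi0)]``
* native pair     ``eps [5 (r0/r)^12 - 6 (r0/r)^10]``  (minimum -eps at r0)
* excluded volume ``eps_rep (sigma_nc / r)^12``, truncated and
  force-shifted at each pair's cutoff so the native pose stays stationary
* COM restraint   ``0.5 k (d - r0)^2`` for inter-chain COM distance d > r0,
  flat inside — a confinement that fixes the effective concentration, not a
  bias on bound states.

The hot kernels are numba-compiled; the public functions wrap them with
validation and named energy terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import BindscapeError
from .structures import ContactMap
from .topology import SBMTopology

# energy-term indices used by the kernels
E_BOND, E_ANGLE, E_DIHEDRAL = 0, 1, 2
E_NATIVE_INTRA, E_NATIVE_INTER = 3, 4
E_REP_INTRA, E_REP_INTER = 5, 6
E_RESTRAINT = 7
N_TERMS = 8

_TERM_NAMES = ("bond", "angle", "dihedral", "native_intra", "native_inter",
               "excluded_intra", "excluded_inter", "restraint")


@njit
def _forces_kernel(coords, f, e,
                   bonds, bond_r0, k_bond,
                   angles, angle_t0, k_angle,
                   dihedrals, dihedral_p0, kd1, kd3,
                   pair_i, pair_j, pair_r0, pair_eps, pair_inter,
                   rep_i, rep_j, rep_inter, rep_rc, sigma_nc, eps_rep,
                   chain_break, use_restraint, restr_r0, restr_k):
    """Fill ``f`` (forces) and ``e`` (per-term energies) in place.
    chain_break is the start index of chain 1 (0 for a single chain)."""
    n = coords.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for t in range(N_TERMS):
        e[t] = 0.0

    # bonds
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e[E_BOND] += k_bond * dr * dr
        fac = -2.0 * k_bond * dr / r
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz

    # angles
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        dt_ = theta - angle_t0[a]
        e[E_ANGLE] += k_angle * dt_ * dt_
        dvdt = 2.0 * k_angle * dt_
        cu = dvdt / (nu * st)
        cv = dvdt / (nv * st)
        fix = -cu * (ct * ux / nu - vx / nv)
        fiy = -cu * (ct * uy / nu - vy / nv)
        fiz = -cu * (ct * uz / nu - vz / nv)
        fkx = -cv * (ct * vx / nv - ux / nu)
        fky = -cv * (ct * vy / nv - uy / nu)
        fkz = -cv * (ct * vz / nv - uz / nu)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz

    # dihedrals
    for t in range(dihedrals.shape[0]):
        i, j, k, l = (dihedrals[t, 0], dihedrals[t, 1],
                      dihedrals[t, 2], dihedrals[t, 3])
        rijx = coords[i, 0] - coords[j, 0]
        rijy = coords[i, 1] - coords[j, 1]
        rijz = coords[i, 2] - coords[j, 2]
        rkjx = coords[k, 0] - coords[j, 0]
        rkjy = coords[k, 1] - coords[j, 1]
        rkjz = coords[k, 2] - coords[j, 2]
        rklx = coords[k, 0] - coords[l, 0]
        rkly = coords[k, 1] - coords[l, 1]
        rklz = coords[k, 2] - coords[l, 2]
        mx = rijy * rkjz - rijz * rkjy
        my = rijz * rkjx - rijx * rkjz
        mz = rijx * rkjy - rijy * rkjx
        nx = rkjy * rklz - rkjz * rkly
        ny = rkjz * rklx - rkjx * rklz
        nz = rkjx * rkly - rkjy * rklx
        m2 = mx * mx + my * my + mz * mz
        n2 = nx * nx + ny * ny + nz * nz
        rkj_n = np.sqrt(rkjx * rkjx + rkjy * rkjy + rkjz * rkjz)
        yv = ((my * nz - mz * ny) * rkjx + (mz * nx - mx * nz) * rkjy
              + (mx * ny - my * nx) * rkjz) / rkj_n
        xv = mx * nx + my * ny + mz * nz
        phi = np.arctan2(yv, xv)
        dphi = phi - dihedral_p0[t]
        e[E_DIHEDRAL] += (kd1 * (1.0 - np.cos(dphi))
                          + kd3 * (1.0 - np.cos(3.0 * dphi)))
        dvdphi = kd1 * np.sin(dphi) + 3.0 * kd3 * np.sin(3.0 * dphi)
        ci = -dvdphi * rkj_n / m2
        cl = dvdphi * rkj_n / n2
        fix, fiy, fiz = ci * mx, ci * my, ci * mz
        flx, fly, flz = cl * nx, cl * ny, cl * nz
        p = (rijx * rkjx + rijy * rkjy + rijz * rkjz) / (rkj_n * rkj_n)
        q = (rklx * rkjx + rkly * rkjy + rklz * rkjz) / (rkj_n * rkj_n)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[l, 0] += flx
        f[l, 1] += fly
        f[l, 2] += flz
        f[j, 0] += (p - 1.0) * fix - q * flx
        f[j, 1] += (p - 1.0) * fiy - q * fly
        f[j, 2] += (p - 1.0) * fiz - q * flz
        f[k, 0] += (q - 1.0) * flx - p * fix
        f[k, 1] += (q - 1.0) * fly - p * fiy
        f[k, 2] += (q - 1.0) * flz - p * fiz

    # native 12-10 pairs
    for p_ in range(pair_i.shape[0]):
        i, j = pair_i[p_], pair_j[p_]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = pair_r0[p_] * pair_r0[p_] / r2
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        ev = pair_eps[p_] * (5.0 * s12 - 6.0 * s10)
        if pair_inter[p_]:
            e[E_NATIVE_INTER] += ev
        else:
            e[E_NATIVE_INTRA] += ev
        fac = -60.0 * pair_eps[p_] * (s10 - s12) / r2
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz

    # excluded volume: truncated, force-shifted so F and V vanish at rc
    for p_ in range(rep_i.shape[0]):
        i, j = rep_i[p_], rep_j[p_]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        rc = rep_rc[p_]
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        s2 = sigma_nc * sigma_nc / r2
        s12 = s2 * s2 * s2 * s2 * s2 * s2
        sc2 = sigma_nc * sigma_nc / (rc * rc)
        sc12 = sc2 * sc2 * sc2 * sc2 * sc2 * sc2
        ev = eps_rep * (s12 - sc12 + 12.0 * sc12 * (r - rc) / rc)
        if rep_inter[p_]:
            e[E_REP_INTER] += ev
        else:
            e[E_REP_INTRA] += ev
        fac = 12.0 * eps_rep * (s12 / r2 - sc12 / (rc * r))
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz

    # one-sided COM restraint between the two chains
    if use_restraint and chain_break > 0:
        n1 = chain_break
        n2 = n - chain_break
        c1x = c1y = c1z = 0.0
        c2x = c2y = c2z = 0.0
        for i in range(n1):
            c1x += coords[i, 0]
            c1y += coords[i, 1]
            c1z += coords[i, 2]
        for i in range(n1, n):
            c2x += coords[i, 0]
            c2y += coords[i, 1]
            c2z += coords[i, 2]
        dx0 = c1x / n1 - c2x / n2
        dx1 = c1y / n1 - c2y / n2
        dx2 = c1z / n1 - c2z / n2
        dcom = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        if dcom > restr_r0:
            dr = dcom - restr_r0
            e[E_RESTRAINT] = 0.5 * restr_k * dr * dr
            fac = -restr_k * dr / dcom
            for i in range(n1):
                f[i, 0] += fac * dx0 / n1
                f[i, 1] += fac * dx1 / n1
                f[i, 2] += fac * dx2 / n1
            for i in range(n1, n):
                f[i, 0] -= fac * dx0 / n2
                f[i, 1] -= fac * dx1 / n2
                f[i, 2] -= fac * dx2 / n2


@njit
def _q_fraction(coords, qi, qj, qr0, tol):
    if qi.shape[0] == 0:
        return np.nan
    formed = 0
    for p in range(qi.shape[0]):
        dx = coords[qi[p]] - coords[qj[p]]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        if r <= tol * qr0[p]:
            formed += 1
    return formed / qi.shape[0]


class KernelArgs:
    """Unpacked topology arrays in the layout the numba kernels expect."""

    __slots__ = ("args", "q_inter", "q_intra1", "q_intra2", "top")

    def __init__(self, top: SBMTopology):
        self.top = top
        chain_break = top.chain_slices[1][0] if top.n_chains == 2 else 0
        use_restr = top.restraint is not None and top.n_chains == 2
        r0 = top.restraint.r0 if use_restr else 0.0
        rk = top.restraint.k if use_restr else 0.0
        ff = top.ff
        self.args = (
            top.bonds, top.bond_r0, ff.k_bond,
            top.angles, top.angle_t0, ff.k_angle,
            top.dihedrals, top.dihedral_p0, ff.k_dihedral_1, ff.k_dihedral_3,
            top.pair_i, top.pair_j, top.pair_r0, top.pair_eps, top.pair_inter,
            top.rep_i, top.rep_j, top.rep_inter, top.rep_rc,
            ff.sigma_nc, ff.epsilon_rep,
            chain_break, use_restr, r0, rk,
        )
        inter = top.pair_inter
        self.q_inter = (top.pair_i[inter], top.pair_j[inter], top.pair_r0[inter])
        n_per = top.chain_slices[0][1]
        in1 = (~inter) & (top.pair_i < n_per)
        in2 = (~inter) & (top.pair_i >= n_per)
        self.q_intra1 = (top.pair_i[in1], top.pair_j[in1], top.pair_r0[in1])
        self.q_intra2 = (top.pair_i[in2], top.pair_j[in2], top.pair_r0[in2])

    def forces(self, coords: np.ndarray):
        f = np.empty((coords.shape[0], 3))
        e = np.empty(N_TERMS)
        _forces_kernel(coords, f, e, *self.args)
        return f, e


@dataclass(frozen=True)
class SimState:
    """Per-term potential energies of one configuration (reduced units)."""

    energies: dict

    @property
    def total(self) -> float:
        return float(sum(self.energies.values()))

    @property
    def e_inter(self) -> float:
        return self.energies["native_inter"] + self.energies["excluded_inter"]

    @property
    def e_intra(self) -> float:
        """Everything internal to the chains: bonded + intra pairs."""
        e = self.energies
        return (e["bond"] + e["angle"] + e["dihedral"]
                + e["native_intra"] + e["excluded_intra"])


def _check_overlap(top: SBMTopology, coords: np.ndarray):
    idx_i = np.concatenate([top.pair_i, top.rep_i, top.bonds[:, 0]])
    idx_j = np.concatenate([top.pair_j, top.rep_j, top.bonds[:, 1]])
    if len(idx_i) == 0:
        return
    d = np.linalg.norm(coords[idx_i] - coords[idx_j], axis=1)
    if np.any(d < 1e-9):
        raise BindscapeError("overlapping beads at (near-)zero distance")


def potential_energy(top: SBMTopology, coords: np.ndarray) -> SimState:
    """Per-term potential energies of ``coords`` under topology ``top``."""
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (top.n_beads, 3):
        raise ValueError(f"coords shape {coords.shape} does not match topology "
                         f"({top.n_beads} beads)")
    _check_overlap(top, coords)
    _, e = KernelArgs(top).forces(coords)
    return SimState(energies=dict(zip(_TERM_NAMES, e.tolist())))


def forces(top: SBMTopology, coords: np.ndarray) -> np.ndarray:
    """Per-bead force vectors, -grad E."""
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (top.n_beads, 3):
        raise ValueError(f"coords shape {coords.shape} does not match topology "
                         f"({top.n_beads} beads)")
    _check_overlap(top, coords)
    f, _ = KernelArgs(top).forces(coords)
    return f


def fraction_native_contacts(coords: np.ndarray, cmap: ContactMap,
                             subset: str = "inter",
                             tolerance_factor: float = 1.2) -> float:
    """Fraction Q of native contacts formed: r <= tol * native_distance.

    ``subset`` is ``"intra"``, ``"inter"`` or ``"all"``; the subset must be
    non-empty.
    """
    sub = cmap.subset(subset)
    if len(sub) == 0:
        raise ValueError(f"contact subset {subset!r} is empty")
    gi = sub.chain_a * cmap.n_per_chain + sub.res_i
    gj = sub.chain_b * cmap.n_per_chain + sub.res_j
    d = np.linalg.norm(coords[gi] - coords[gj], axis=1)
    return float(np.mean(d <= tolerance_factor * sub.native_distance))
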