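"""Langevin dynamics of the SBM in flexible or rigid-chain mode.

Flexible chains are propagated with the BAOAB splitting of the Langevin
equation (all bead masses 1, kB = 1).  In rigid-chain mode each chain is a
rigid body: translation of the COM plus rotation about it, integrated with
the same B-A-O-A-B pattern where the A step advances the quaternion by the
body-frame angular velocity (with an explicit torque-free Euler correction
for precession) and the O step thermostats the angular momentum per
principal axis.  With friction 0 the flexible integrator reduces to plain
velocity Verlet.

Trajectories record total/interfacial/internal potential energy, kinetic
energy, native-contact fractions Qb and Qf per chain, and the inter-chain
COM distance at a fixed sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .energy import KernelArgs, _forces_kernel, _q_fraction
from .errors import IntegrationError
from .topology import SBMTopology

_E_GUARD = 1e10


# ---------------------------------------------------------------------------
# quaternion helpers (w, x, y, z convention)

@njit(inline="always")
def _quat_mul(a, b):
    out = np.empty(4)
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]
    return out


@njit(inline="always")
def _quat_to_mat(q):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R = np.empty((3, 3))
    R[0, 0] = 1 - 2 * (y * y + z * z)
    R[0, 1] = 2 * (x * y - w * z)
    R[0, 2] = 2 * (x * z + w * y)
    R[1, 0] = 2 * (x * y + w * z)
    R[1, 1] = 1 - 2 * (x * x + z * z)
    R[1, 2] = 2 * (y * z - w * x)
    R[2, 0] = 2 * (x * z - w * y)
    R[2, 1] = 2 * (y * z + w * x)
    R[2, 2] = 1 - 2 * (x * x + y * y)
    return R


@njit(inline="always")
def _rotate_quat(q, w_body, h):
    """Advance orientation by body angular velocity w_body over time h."""
    wn = np.sqrt(w_body[0] ** 2 + w_body[1] ** 2 + w_body[2] ** 2)
    if wn < 1e-14:
        return q
    half = 0.5 * wn * h
    s = np.sin(half) / wn
    dq = np.empty(4)
    dq[0] = np.cos(half)
    dq[1] = s * w_body[0]
    dq[2] = s * w_body[1]
    dq[3] = s * w_body[2]
    out = _quat_mul(q, dq)
    norm = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
    return out / norm


# ---------------------------------------------------------------------------
# integrator kernels

@njit
def _record(out, s, step, e, ke, coords, chain_break,
            qii, qij, qir, q1i, q1j, q1r, q2i, q2j, q2r, tol):
    out[s, 0] = step
    etot = e[0] + e[1] + e[2] + e[3] + e[4] + e[5] + e[6] + e[7]
    out[s, 1] = etot
    out[s, 2] = e[4] + e[6]                          # interfacial
    out[s, 3] = e[0] + e[1] + e[2] + e[3] + e[5]     # internal
    out[s, 9] = e[0] + e[1] + e[2]                   # bonded only
    out[s, 4] = ke
    out[s, 5] = _q_fraction(coords, qii, qij, qir, tol)
    out[s, 6] = _q_fraction(coords, q1i, q1j, q1r, tol)
    out[s, 7] = _q_fraction(coords, q2i, q2j, q2r, tol)
    if chain_break > 0:
        n = coords.shape[0]
        c1 = np.zeros(3)
        c2 = np.zeros(3)
        for i in range(chain_break):
            for d in range(3):
                c1[d] += coords[i, d]
        for i in range(chain_break, n):
            for d in range(3):
                c2[d] += coords[i, d]
        dd = 0.0
        for d in range(3):
            dd += (c1[d] / chain_break - c2[d] / (n - chain_break)) ** 2
        out[s, 8] = np.sqrt(dd)
    else:
        out[s, 8] = np.nan
    return etot


@njit
def _run_flexible(x, v, n_steps, dt, T, gamma, seed, sample_every,
                  bonds, bond_r0, k_bond,
                  angles, angle_t0, k_angle,
                  dihedrals, dihedral_p0, kd1, kd3,
                  pair_i, pair_j, pair_r0, pair_eps, pair_inter,
                  rep_i, rep_j, rep_inter, rep_rc, sigma_nc, eps_rep,
                  chain_break, use_restraint, restr_r0, restr_k,
                  qii, qij, qir, q1i, q1j, q1r, q2i, q2j, q2r, tol):
    np.random.seed(seed)
    n = x.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * T)
    n_samples = n_steps // sample_every + 1
    out = np.empty((n_samples, 10))
    f = np.empty((n, 3))
    e = np.empty(8)
    _forces_kernel(x, f, e, bonds, bond_r0, k_bond, angles, angle_t0, k_angle,
                   dihedrals, dihedral_p0, kd1, kd3,
                   pair_i, pair_j, pair_r0, pair_eps, pair_inter,
                   rep_i, rep_j, rep_inter, rep_rc, sigma_nc, eps_rep,
                   chain_break, use_restraint, restr_r0, restr_k)
    ke = 0.5 * np.sum(v * v)
    _record(out, 0, 0, e, ke, x, chain_break,
            qii, qij, qir, q1i, q1j, q1r, q2i, q2j, q2r, tol)
    s = 1
    for step in range(1, n_steps + 1):
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d]
                x[i, d] += 0.5 * dt * v[i, d]
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    v[i, d] = c1 * v[i, d] + c2 * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                x[i, d] += 0.5 * dt * v[i, d]
        _forces_kernel(x, f, e, bonds, bond_r0, k_bond, angles, angle_t0,
                       k_angle, dihedrals, dihedral_p0, kd1, kd3,
                       pair_i, pair_j, pair_r0, pair_eps, pair_inter,
                       rep_i, rep_j, rep_inter, rep_rc, sigma_nc, eps_rep,
                       chain_break, use_restraint, restr_r0, restr_k)
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d]
        if step % sample_every == 0:
            ke = 0.5 * np.sum(v * v)
            etot = _record(out, s, step, e, ke, x, chain_break,
                           qii, qij, qir, q1i, q1j, q1r, q2i, q2j, q2r, tol)
            s += 1
            if not np.isfinite(etot) or np.abs(etot) > _E_GUARD:
                return out[:s], 1
    return out[:s], 0


@njit
def _rigid_coords(xc, qq, refc, n_per):
    n = refc.shape[0]
    coords = np.empty((n, 3))
    for c in range(2):
        R = _quat_to_mat(qq[c])
        for i in range(n_per):
            gi = c * n_per + i
            for d in range(3):
                coords[gi, d] = (xc[c, d] + R[d, 0] * refc[gi, 0]
                                 + R[d, 1] * refc[gi, 1] + R[d, 2] * refc[gi, 2])
    return coords


@njit
def _rigid_force_torque(coords, f, xc, qq, n_per):
    """Net force and body-frame torque per chain."""
    F = np.zeros((2, 3))
    tau_b = np.zeros((2, 3))
    for c in range(2):
        R = _quat_to_mat(qq[c])
        tl = np.zeros(3)
        for i in range(n_per):
            gi = c * n_per + i
            rx = coords[gi, 0] - xc[c, 0]
            ry = coords[gi, 1] - xc[c, 1]
            rz = coords[gi, 2] - xc[c, 2]
            F[c, 0] += f[gi, 0]
            F[c, 1] += f[gi, 1]
            F[c, 2] += f[gi, 2]
            tl[0] += ry * f[gi, 2] - rz * f[gi, 1]
            tl[1] += rz * f[gi, 0] - rx * f[gi, 2]
            tl[2] += rx * f[gi, 1] - ry * f[gi, 0]
        for d in range(3):
            tau_b[c, d] = R[0, d] * tl[0] + R[1, d] * tl[1] + R[2, d] * tl[2]
    return F, tau_b


@njit(inline="always")
def _rigid_A(xc, vc, qq, Lb, Ip, h):
    for c in range(2):
        for d in range(3):
            xc[c, d] += h * vc[c, d]
        w = np.empty(3)
        for d in range(3):
            w[d] = Lb[c, d] / Ip[c, d]
        # torque-free precession: dL/dt = L x w (midpoint step)
        Lm = np.empty(3)
        Lm[0] = Lb[c, 0] + 0.5 * h * (Lb[c, 1] * w[2] - Lb[c, 2] * w[1])
        Lm[1] = Lb[c, 1] + 0.5 * h * (Lb[c, 2] * w[0] - Lb[c, 0] * w[2])
        Lm[2] = Lb[c, 2] + 0.5 * h * (Lb[c, 0] * w[1] - Lb[c, 1] * w[0])
        wm = np.empty(3)
        for d in range(3):
            wm[d] = Lm[d] / Ip[c, d]
        Lb[c, 0] += h * (Lm[1] * wm[2] - Lm[2] * wm[1])
        Lb[c, 1] += h * (Lm[2] * wm[0] - Lm[0] * wm[2])
        Lb[c, 2] += h * (Lm[0] * wm[1] - Lm[1] * wm[0])
        qq[c] = _rotate_quat(qq[c], wm, h)


@njit
def _run_rigid(xc, vc, qq, Lb, refc, Ip, n_per,
               n_steps, dt, T, gamma, seed, sample_every,
               bonds, bond_r0, k_bond,
               angles, angle_t0, k_angle,
               dihedrals, dihedral_p0, kd1, kd3,
               pair_i, pair_j, pair_r0, pair_eps, pair_inter,
               rep_i, rep_j, rep_inter, rep_rc, sigma_nc, eps_rep,
               chain_break, use_restraint, restr_r0, restr_k,
               qii, qij, qir, q1i, q1j, q1r, q2i, q2j, q2r, tol):
    np.random.seed(seed)
    M = float(n_per)
    c1 = np.exp(-gamma * dt)
    c2v = np.sqrt((1.0 - c1 * c1) * T / M)
    n_samples = n_steps // sample_every + 1
    out = np.empty((n_samples, 10))
    coords = _rigid_coords(xc, qq, refc, n_per)
    f = np.empty((refc.shape[0], 3))
    e = np.empty(8)
    _forces_kernel(coords, f, e, bonds, bond_r0, k_bond, angles, angle_t0,
                   k_angle, dihedrals, dihedral_p0, kd1, kd3,
                   pair_i, pair_j, pair_r0, pair_eps, pair_inter,
                   rep_i, rep_j, rep_inter, rep_rc, sigma_nc, eps_rep,
                   chain_break, use_restraint, restr_r0, restr_k)
    F, tau = _rigid_force_torque(coords, f, xc, qq, n_per)
    ke = 0.0
    for c in range(2):
        for d in range(3):
            ke += 0.5 * M * vc[c, d] ** 2 + 0.5 * Lb[c, d] ** 2 / Ip[c, d]
    _record(out, 0, 0, e, ke, coords, chain_break,
            qii, qij, qir, q1i, q1j, q1r, q2i, q2j, q2r, tol)
    s = 1
    for step in range(1, n_steps + 1):
        for c in range(2):
            for d in range(3):
                vc[c, d] += 0.5 * dt * F[c, d] / M
                Lb[c, d] += 0.5 * dt * tau[c, d]
        _rigid_A(xc, vc, qq, Lb, Ip, 0.5 * dt)
        if gamma > 0.0:
            for c in range(2):
                for d in range(3):
                    vc[c, d] = c1 * vc[c, d] + c2v * np.random.standard_normal()
                    Lb[c, d] = (c1 * Lb[c, d]
                                + np.sqrt((1.0 - c1 * c1) * T * Ip[c, d])
                                * np.random.standard_normal())
        _rigid_A(xc, vc, qq, Lb, Ip, 0.5 * dt)
        coords = _rigid_coords(xc, qq, refc, n_per)
        _forces_kernel(coords, f, e, bonds, bond_r0, k_bond, angles, angle_t0,
                       k_angle, dihedrals, dihedral_p0, kd1, kd3,
                       pair_i, pair_j, pair_r0, pair_eps, pair_inter,
                       rep_i, rep_j, rep_inter, rep_rc, sigma_nc, eps_rep,
                       chain_break, use_restraint, restr_r0, restr_k)
        F, tau = _rigid_force_torque(coords, f, xc, qq, n_per)
        for c in range(2):
            for d in range(3):
                vc[c, d] += 0.5 * dt * F[c, d] / M
                Lb[c, d] += 0.5 * dt * tau[c, d]
        if step % sample_every == 0:
            ke = 0.0
            for c in range(2):
                for d in range(3):
                    ke += 0.5 * M * vc[c, d] ** 2 + 0.5 * Lb[c, d] ** 2 / Ip[c, d]
            etot = _record(out, s, step, e, ke, coords, chain_break,
                           qii, qij, qir, q1i, q1j, q1r, q2i, q2j, q2r, tol)
            s += 1
            if not np.isfinite(etot) or np.abs(etot) > _E_GUARD:
                return out[:s], 1
    return out[:s], 0


@njit
def _run_harmonic_1d(k, T, n_steps, dt, gamma, seed, sample_every):
    """1-D bead in V = k x^2 / 2 under BAOAB: thermostat validation oracle."""
    np.random.seed(seed)
    x, v = 0.0, 0.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * T)
    n_samples = n_steps // sample_every
    xs = np.empty(n_samples)
    f = -k * x
    s = 0
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.standard_normal()
        x += 0.5 * dt * v
        f = -k * x
        v += 0.5 * dt * f
        if step % sample_every == 0:
            xs[s] = x
            s += 1
    return xs


# ---------------------------------------------------------------------------
# python-level containers and drivers

@dataclass(frozen=True)
class Trajectory:
    """Sampled time series of one Langevin run (reduced units)."""

    step: np.ndarray
    e_total: np.ndarray       # total potential incl. restraint
    e_inter: np.ndarray       # interfacial native + excluded
    e_intra: np.ndarray       # bonded + intra native + intra excluded
    e_kin: np.ndarray
    qb: np.ndarray
    qf1: np.ndarray
    qf2: np.ndarray
    com_distance: np.ndarray
    temperature: float
    dt: float
    seed: int
    sample_every: int
    e_bonded: np.ndarray | None = None

    def __post_init__(self):
        if len(self.step) > 1 and not np.all(np.diff(self.step) > 0):
            raise ValueError("sample steps must be strictly increasing")
        for q in (self.qb, self.qf1, self.qf2):
            ok = np.isnan(q) | ((q >= 0.0) & (q <= 1.0))
            if not np.all(ok):
                raise ValueError("Q outside [0, 1]")

    def __len__(self) -> int:
        return len(self.step)

    @property
    def e_conf(self) -> np.ndarray:
        """Conformational energy: interfacial + internal, no restraint."""
        return self.e_inter + self.e_intra

    @property
    def e_contact_intra(self) -> np.ndarray:
        """Intra-chain contact energy (native + excluded), bonded terms
        removed: the folding landscape energy."""
        return self.e_intra - self.e_bonded

    @property
    def e_contact(self) -> np.ndarray:
        """All contact energy (interfacial + intra-chain), the global
        binding-folding landscape energy."""
        return self.e_inter + self.e_contact_intra


@dataclass
class FlexState:
    coords: np.ndarray
    velocities: np.ndarray

    def scale_velocities(self, factor: float):
        self.velocities = self.velocities * factor


@dataclass
class RigidState:
    xc: np.ndarray   # (2,3) chain COMs
    vc: np.ndarray   # (2,3)
    q: np.ndarray    # (2,4) orientation quaternions, w-first
    Lb: np.ndarray   # (2,3) body-frame angular momenta

    def scale_velocities(self, factor: float):
        self.vc = self.vc * factor
        self.Lb = self.Lb * factor


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    x, y, z, w = Rotation.from_matrix(R).as_quat()
    return np.array([w, x, y, z])


class RigidBasis:
    """Per-chain principal-axis frames of a two-chain topology."""

    def __init__(self, top: SBMTopology):
        if top.n_chains != 2:
            raise ValueError("rigid-chain dynamics requires exactly 2 chains")
        self.n_per = top.chain_slices[0][1]
        self.refc = np.empty((top.n_beads, 3))
        self.Ip = np.empty((2, 3))
        self.q0 = np.empty((2, 4))
        self.com0 = np.empty((2, 3))
        for c, (a, b) in enumerate(top.chain_slices):
            xyz = top.native_coords[a:b]
            com = xyz.mean(axis=0)
            cen = xyz - com
            inertia = np.einsum("ni,ni->", cen, cen) * np.eye(3) - cen.T @ cen
            vals, vecs = np.linalg.eigh(inertia)
            if np.linalg.det(vecs) < 0:  # keep a proper rotation
                vecs[:, 0] = -vecs[:, 0]
            self.refc[a:b] = cen @ vecs
            self.Ip[c] = np.maximum(vals, 1e-10)
            self.q0[c] = _quat_from_matrix(vecs)
            self.com0[c] = com

    def native_state(self) -> RigidState:
        return RigidState(xc=self.com0.copy(), vc=np.zeros((2, 3)),
                          q=self.q0.copy(), Lb=np.zeros((2, 3)))

    def coords_of(self, state: RigidState) -> np.ndarray:
        return _rigid_coords(state.xc, state.q, self.refc, self.n_per)


def _maxwell_state(top: SBMTopology, T: float, rng) -> FlexState:
    v = rng.normal(0.0, np.sqrt(T), size=(top.n_beads, 3))
    return FlexState(coords=top.native_coords.copy(), velocities=v)


def _maxwell_rigid_state(basis: RigidBasis, T: float, rng) -> RigidState:
    st = basis.native_state()
    st.vc = rng.normal(0.0, np.sqrt(T / basis.n_per), size=(2, 3))
    st.Lb = rng.normal(0.0, 1.0, size=(2, 3)) * np.sqrt(T * basis.Ip)
    return st


def _traj_from_out(out, T, dt, seed, sample_every, rigid):
    qf1, qf2 = out[:, 6].copy(), out[:, 7].copy()
    if rigid:  # chains frozen in their native fold
        qf1[:] = 1.0
        qf2[:] = 1.0
    return Trajectory(step=out[:, 0].astype(int), e_total=out[:, 1],
                      e_inter=out[:, 2], e_intra=out[:, 3], e_kin=out[:, 4],
                      qb=out[:, 5], qf1=qf1, qf2=qf2, com_distance=out[:, 8],
                      temperature=T, dt=dt, seed=seed,
                      sample_every=sample_every, e_bonded=out[:, 9])


def langevin_run(top: SBMTopology, T: float, n_steps: int, *,
                 dt: float = 5e-4, friction: float = 1.0,
                 seed: int, sample_every: int = 100,
                 state=None, basis: RigidBasis | None = None,
                 tolerance_factor: float = 1.2):
    """Langevin trajectory of ``top`` at temperature ``T``.

    Returns ``(Trajectory, final_state)``; with ``n_steps=0`` the trajectory
    holds only the initial sample.  A fixed seed gives a bit-identical
    trajectory.  Rigid-chain topologies are propagated as rigid bodies.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    ka = KernelArgs(top)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 91]))
    int_seed = int(rng.integers(0, 2**31 - 1))
    rigid = top.mode == "rigid_chains"
    if rigid:
        basis = basis or RigidBasis(top)
        if state is None:
            state = _maxwell_rigid_state(basis, T, rng)
        out, status = _run_rigid(
            state.xc, state.vc, state.q, state.Lb, basis.refc, basis.Ip,
            basis.n_per, n_steps, dt, T, friction, int_seed, sample_every,
            *ka.args, *ka.q_inter, *ka.q_intra1, *ka.q_intra2, tolerance_factor)
    else:
        if state is None:
            state = _maxwell_state(top, T, rng)
        out, status = _run_flexible(
            state.coords, state.velocities, n_steps, dt, T, friction,
            int_seed, sample_every,
            *ka.args, *ka.q_inter, *ka.q_intra1, *ka.q_intra2, tolerance_factor)
    if status != 0:
        raise IntegrationError(
            f"trajectory diverged (|E| > {_E_GUARD:g}) at dt={dt}; "
            "reduce the time step")
    return _traj_from_out(out, T, dt, seed, sample_every, rigid), state


def harmonic_reference_run(k: float, T: float, n_steps: int, *,
                           dt: float = 5e-4, friction: float = 1.0,
                           seed: int, sample_every: int = 10) -> np.ndarray:
    """Positions of a 1-D harmonic bead (V = k x^2 / 2) under the same
    BAOAB thermostat; equilibrium position variance is T/k."""
    return _run_harmonic_1d(k, T, n_steps, dt, friction, seed & 0x7FFFFFFF,
                            sample_every)
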