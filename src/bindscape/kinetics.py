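"""Binding kinetics: first-passage times from dissociated starts.

An ensemble of independent constant-temperature Langevin trajectories is
launched from randomized dissociated configurations (chain COMs separated
to near the confinement radius, random orientations; flexible chains are
additionally randomized by a short high-temperature burst).  The
first-passage time (FPT) to the bound state — Qb at or above a threshold,
held for a debounce window so transient collisions do not count — is
collected per trajectory, and the mean first-passage time (MFPT) over the
uncensored trajectories is the binding time; its inverse is the
association rate (the kinetic specificity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .dynamics import (FlexState, RigidBasis, RigidState, _quat_from_matrix,
                       langevin_run)
from .errors import EstimationError
from .topology import SBMTopology

DEFAULT_N_TRAJ = 200
DEFAULT_Q_THRESHOLD = 0.8
DEFAULT_HOLD_SAMPLES = 100


@dataclass(frozen=True)
class FirstPassageEnsemble:
    """Per-trajectory binding first-passage times (steps; NaN = censored)."""

    temperature: float
    fpt_steps: np.ndarray
    q_threshold: float
    hold_samples: int
    max_steps: int
    seed: int

    def __post_init__(self):
        arr = np.asarray(self.fpt_steps, dtype=float)
        object.__setattr__(self, "fpt_steps", arr)
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError("first-passage times must be non-negative")

    @property
    def n_traj(self) -> int:
        return len(self.fpt_steps)

    def summary(self):
        return mfpt(self)


def mfpt(ensemble) -> tuple[float, float, float]:
    """(mean, standard error, censored fraction) of first-passage times.

    Accepts a :class:`FirstPassageEnsemble` or a raw sequence where
    censored trajectories are NaN.  The mean and SE run over uncensored
    trajectories only.
    """
    fpts = (ensemble.fpt_steps if isinstance(ensemble, FirstPassageEnsemble)
            else np.asarray(ensemble, dtype=float))
    if fpts.size == 0:
        raise EstimationError("no first-passage times recorded")
    ok = np.isfinite(fpts)
    if not np.any(ok):
        raise EstimationError("all trajectories censored; no MFPT")
    x = fpts[ok]
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
    return mean, se, float(1.0 - len(x) / len(fpts))


def kinetic_comparison(rigid: FirstPassageEnsemble,
                       flexible: FirstPassageEnsemble
                       ) -> tuple[float, float]:
    """Binding-time ratio MFPT_rigid / MFPT_flexible with propagated SE.

    A ratio above 1 means flexibility accelerates binding (fly-casting);
    below 1, monomer folding is rate-limiting and rigid binding is faster.
    """
    m_r, se_r, _ = mfpt(rigid)
    m_f, se_f, _ = mfpt(flexible)
    ratio = m_r / m_f
    rel = 0.0
    for m, se in ((m_r, se_r), (m_f, se_f)):
        if np.isfinite(se):
            rel += (se / m) ** 2
    return float(ratio), float(ratio * np.sqrt(rel))


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_quat(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _min_interchain_distance(coords: np.ndarray, n_per: int) -> float:
    d = np.linalg.norm(coords[:n_per, None] - coords[None, n_per:], axis=-1)
    return float(d.min())


def _dissociated_flex(top: SBMTopology, T: float, rng) -> FlexState:
    n_per = top.chain_slices[0][1]
    r0 = top.restraint.r0 if top.restraint is not None else 6.0
    for _ in range(200):  # reject clashing placements
        coords = top.native_coords.copy()
        sep = rng.uniform(0.75, 1.0) * r0
        direction = _random_unit(rng)
        for c, (a, b) in enumerate(top.chain_slices):
            com = coords[a:b].mean(axis=0)
            R = Rotation.from_quat(np.roll(_random_quat(rng), -1)).as_matrix()
            coords[a:b] = (coords[a:b] - com) @ R.T
            coords[a:b] += direction * sep if c == 1 else 0.0
        if _min_interchain_distance(coords, n_per) > 0.45:
            break
    v = rng.normal(0.0, np.sqrt(T), size=(top.n_beads, 3))
    return FlexState(coords=coords, velocities=v)


def _dissociated_rigid(top: SBMTopology, basis: RigidBasis, T: float,
                       rng) -> RigidState:
    st = basis.native_state()
    r0 = top.restraint.r0 if top.restraint is not None else 6.0
    for _ in range(200):  # reject clashing placements
        sep = rng.uniform(0.75, 1.0) * r0
        direction = _random_unit(rng)
        st.xc[0] = np.zeros(3)
        st.xc[1] = direction * sep
        for c in range(2):
            q_rand = _random_quat(rng)
            Rr = Rotation.from_quat(np.roll(q_rand, -1)).as_matrix()
            st.q[c] = _quat_from_matrix(
                Rr @ Rotation.from_quat(np.roll(basis.q0[c], -1)).as_matrix())
        coords = basis.coords_of(st)
        if _min_interchain_distance(coords, basis.n_per) > 0.45:
            break
    st.vc = rng.normal(0.0, np.sqrt(T / basis.n_per), size=(2, 3))
    st.Lb = rng.normal(size=(2, 3)) * np.sqrt(T * basis.Ip)
    return st


def _one_fpt(top, basis, T, max_steps, q_threshold, hold_samples, rng,
             dt, friction, sample_every, chunk_steps, burst_steps, burst_T):
    rigid = top.mode == "rigid_chains"
    if rigid:
        state = _dissociated_rigid(top, basis, T, rng)
    else:
        state = _dissociated_flex(top, T, rng)
        if burst_steps > 0:  # randomize internal coordinates
            _, state = langevin_run(top, burst_T, burst_steps, dt=dt,
                                    friction=friction,
                                    seed=int(rng.integers(2**31 - 1)),
                                    sample_every=burst_steps, state=state)
            state.velocities = rng.normal(0.0, np.sqrt(T),
                                          size=state.velocities.shape)
    held = 0
    win_start = -1
    steps_done = 0
    first = True
    while steps_done < max_steps:
        seg = int(min(chunk_steps, max_steps - steps_done))
        traj, state = langevin_run(top, T, seg, dt=dt, friction=friction,
                                   seed=int(rng.integers(2**31 - 1)),
                                   sample_every=sample_every, state=state,
                                   basis=basis)
        qb = traj.qb if first else traj.qb[1:]
        steps = traj.step if first else traj.step[1:]
        for q, s in zip(qb, steps):
            gs = steps_done + int(s)  # traj steps are segment-local
            if q >= q_threshold:
                if held == 0:
                    win_start = gs
                held += 1
                if held >= hold_samples:
                    return float(win_start)
            else:
                held = 0
        steps_done += seg
        first = False
    return float("nan")


def run_first_passage(top: SBMTopology, T: float, n_traj: int = DEFAULT_N_TRAJ,
                      max_steps: int = 10**8, *,
                      q_threshold: float = DEFAULT_Q_THRESHOLD,
                      hold_samples: int = DEFAULT_HOLD_SAMPLES,
                      seed: int, dt: float = 5e-4, friction: float = 1.0,
                      sample_every: int = 100, chunk_steps: int = 20000,
                      burst_steps: int = 2000, burst_T: float = 2.2
                      ) -> FirstPassageEnsemble:
    """First-passage ensemble of ``n_traj`` independent binding runs.

    Each trajectory starts dissociated (COM separation near the
    confinement radius, random orientations), runs at constant ``T`` and
    stops when Qb >= ``q_threshold`` holds for ``hold_samples``
    consecutive samples; the FPT is the first step of that window.
    Trajectories that never bind within ``max_steps`` are censored (NaN).
    """
    if n_traj < 1:
        raise ValueError("need at least one trajectory")
    if top.n_inter_pairs == 0:
        raise EstimationError(
            "binding stop rule unreachable: topology has no inter-chain "
            "native pairs")
    basis = RigidBasis(top) if top.mode == "rigid_chains" else None
    fpts = np.empty(n_traj)
    for k in range(n_traj):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, k]))
        fpts[k] = _one_fpt(top, basis, T, max_steps, q_threshold,
                           hold_samples, rng, dt, friction,
                           sample_every, chunk_steps, burst_steps, burst_T)
    return FirstPassageEnsemble(temperature=T, fpt_steps=fpts,
                                q_threshold=q_threshold,
                                hold_samples=hold_samples,
                                max_steps=max_steps, seed=seed)
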