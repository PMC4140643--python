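"""Temperature replica exchange over Langevin replicas.

Replicas run independently between exchange attempts; neighbouring pairs
then attempt a Metropolis swap of configurations with the standard
criterion accept iff u < min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)]).  Sweeps
alternate between even and odd neighbour pairs, velocities are rescaled by
sqrt(T_new/T_old) on accepted swaps, and each replica segment draws from
its own explicitly seeded stream, so results are reproducible under any
scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import RigidBasis, Trajectory, langevin_run
from .energy import potential_energy
from .errors import BindscapeError
from .topology import SBMTopology

#: default ladder parameters
DEFAULT_N_TEMPS = 48
DEFAULT_T_MIN = 0.2
DEFAULT_T_MAX = 2.2
DEFAULT_EXCHANGE_INTERVAL = 20000

_SAMPLE_FIELDS = ("e_total", "e_inter", "e_intra", "e_conf",
                  "e_contact_intra", "e_contact",
                  "qb", "qf1", "qf2", "com_distance")


def default_ladder(n_temps: int = DEFAULT_N_TEMPS,
                   t_min: float = DEFAULT_T_MIN,
                   t_max: float = DEFAULT_T_MAX) -> np.ndarray:
    """Geometric temperature ladder (default 48 temperatures, 0.2-2.2)."""
    return np.geomspace(t_min, t_max, n_temps)


def metropolis_exchange(E_i: float, T_i: float, E_j: float, T_j: float,
                        u: float) -> bool:
    """Replica-exchange acceptance for one neighbour pair.

    Accept iff u < min(1, exp(Delta)) with
    Delta = (1/T_i - 1/T_j) (E_i - E_j).
    """
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    if T_i == T_j:
        raise ValueError("exchange requires distinct temperatures")
    delta = (1.0 / T_i - 1.0 / T_j) * (E_i - E_j)
    if delta >= 0:
        return u < 1.0
    return u < np.exp(delta)


@dataclass
class ReplicaEnsemble:
    """Per-temperature sample sets and exchange statistics."""

    ladder: np.ndarray
    samples: list            # per T: dict field -> 1-D array
    attempts: np.ndarray     # (nT-1,)
    accepts: np.ndarray      # (nT-1,)
    seed: int
    exchange_interval: int
    sample_every: int

    def __post_init__(self):
        self.ladder = np.asarray(self.ladder, dtype=float)
        if len(self.ladder) > 1 and not np.all(np.diff(self.ladder) > 0):
            raise BindscapeError("temperature ladder must be strictly increasing")
        if np.any(self.accepts > self.attempts):
            raise BindscapeError("acceptance counts exceed attempts")

    @property
    def n_temps(self) -> int:
        return len(self.ladder)

    def acceptance_ratios(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0,
                            self.accepts / np.maximum(self.attempts, 1), np.nan)

    def field(self, name: str, burn_in: float = 0.0) -> list[np.ndarray]:
        """Per-temperature arrays of one sampled field, burn-in removed."""
        out = []
        for s in self.samples:
            x = s[name]
            out.append(x[int(len(x) * burn_in):])
        return out


def _append_samples(store: dict, traj: Trajectory, skip_first: bool):
    sl = slice(1, None) if skip_first else slice(None)
    for f in _SAMPLE_FIELDS:
        store[f].append(getattr(traj, f)[sl])


def run_remd(top: SBMTopology, ladder=None, n_steps: int = 200000,
             exchange_interval: int = DEFAULT_EXCHANGE_INTERVAL, *,
             seed: int, dt: float = 5e-4, friction: float = 1.0,
             sample_every: int = 100,
             tolerance_factor: float = 1.2) -> ReplicaEnsemble:
    """Replica-exchange Langevin dynamics of ``top``.

    ``n_steps`` is the step count per replica; exchanges are attempted
    every ``exchange_interval`` steps between neighbouring temperatures.
    Fixed ``seed`` makes the whole ensemble deterministic.
    """
    ladder = default_ladder() if ladder is None else np.asarray(ladder, float)
    if len(ladder) < 1:
        raise ValueError("ladder must contain at least one temperature")
    n_temps = len(ladder)
    basis = RigidBasis(top) if top.mode == "rigid_chains" else None
    master = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    states = [None] * n_temps
    stores = [{f: [] for f in _SAMPLE_FIELDS} for _ in range(n_temps)]
    attempts = np.zeros(n_temps - 1, dtype=int)
    accepts = np.zeros(n_temps - 1, dtype=int)

    n_blocks = max(1, int(np.ceil(n_steps / exchange_interval)))
    steps_done = 0
    for block in range(n_blocks):
        seg = min(exchange_interval, n_steps - steps_done)
        last_E = np.empty(n_temps)
        for t in range(n_temps):
            seg_seed = int(np.random.SeedSequence(
                [seed & 0x7FFFFFFF, t, block]).generate_state(1)[0] % 2**31)
            try:
                traj, states[t] = langevin_run(
                    top, float(ladder[t]), seg, dt=dt, friction=friction,
                    seed=seg_seed, sample_every=sample_every,
                    state=states[t], basis=basis,
                    tolerance_factor=tolerance_factor)
            except BindscapeError as exc:
                raise BindscapeError(f"replica {t} (T={ladder[t]:.4g}): {exc}"
                                     ) from exc
            _append_samples(stores[t], traj, skip_first=block > 0)
            # exchange uses the energy of the state actually swapped
            coords = (basis.coords_of(states[t]) if basis is not None
                      else states[t].coords)
            last_E[t] = potential_energy(top, coords).total
        steps_done += seg
        # alternating even/odd neighbour sweeps
        for p in range(block % 2, n_temps - 1, 2):
            attempts[p] += 1
            u = float(master.uniform())
            if metropolis_exchange(last_E[p], float(ladder[p]),
                                   last_E[p + 1], float(ladder[p + 1]), u):
                accepts[p] += 1
                states[p], states[p + 1] = states[p + 1], states[p]
                states[p].scale_velocities(np.sqrt(ladder[p] / ladder[p + 1]))
                states[p + 1].scale_velocities(np.sqrt(ladder[p + 1] / ladder[p]))
                last_E[p], last_E[p + 1] = last_E[p + 1], last_E[p]

    samples = [{f: np.concatenate(stores[t][f]) for f in _SAMPLE_FIELDS}
               for t in range(n_temps)]
    return ReplicaEnsemble(ladder=ladder, samples=samples, attempts=attempts,
                           accepts=accepts, seed=seed,
                           exchange_interval=exchange_interval,
                           sample_every=sample_every)


def ensemble_histograms(ens: ReplicaEnsemble, *, energy_key: str = "e_inter",
                        q_key: str | None = "qb", n_contacts: int | None = None,
                        n_energy_bins: int = 200, burn_in: float = 0.2):
    """Per-temperature (E[, Q]) histograms for WHAM.

    Q samples are mapped to the natural contact-count grid k/N (N+1 bins),
    which requires ``n_contacts`` when ``q_key`` is given.  Returns
    ``(hist, energy_edges, q_values)`` with hist shaped (nT, nE, nQ).
    """
    E = ens.field(energy_key, burn_in)
    lo = min(e.min() for e in E)
    hi = max(e.max() for e in E)
    span = hi - lo if hi > lo else 1.0
    edges = np.linspace(lo - 1e-9 * span, hi + 1e-9 * span, n_energy_bins + 1)
    if q_key is None:
        hist = np.stack([np.histogram(e, bins=edges)[0] for e in E])
        return hist[:, :, None].astype(float), edges, None
    if n_contacts is None:
        raise ValueError("n_contacts required to bin Q on the contact grid")
    Q = ens.field(q_key, burn_in)
    q_values = np.arange(n_contacts + 1) / n_contacts
    hist = np.zeros((ens.n_temps, n_energy_bins, n_contacts + 1))
    for t, (e, q) in enumerate(zip(E, Q)):
        k = np.clip(np.rint(q * n_contacts).astype(int), 0, n_contacts)
        for kk in range(n_contacts + 1):
            sel = k == kk
            if np.any(sel):
                hist[t, :, kk] = np.histogram(e[sel], bins=edges)[0]
    return hist, edges, q_values
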