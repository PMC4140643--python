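"""Structure-based (Go-like) C-alpha topologies.

The potential is the standard C-alpha structure-based model: harmonic bonds
and angles, (1,3)-cosine dihedrals, 12-10 Lennard-Jones-like wells on native
pairs and a purely repulsive excluded volume on all remaining non-bonded
pairs.  All constants are in reduced units; the native structure is the
global minimum by construction.

Two modes are supported.  ``flexible`` keeps all intra-chain degrees of
freedom.  ``rigid_chains`` freezes each monomer into a rigid body: bonded
terms and intra-chain pairs are removed exactly and only the *identical*
inter-chain native and excluded-volume interactions remain, so the rigid
and flexible landscapes share the same interfacial energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyError
from .structures import ContactMap, DimerStructure


@dataclass(frozen=True)
class ForceField:
    """Reduced-unit force-field constants (Clementi-style C-alpha SBM)."""

    k_bond: float = 100.0
    k_angle: float = 20.0
    k_dihedral_1: float = 1.0
    k_dihedral_3: float = 0.5
    epsilon: float = 1.0        # native-pair well depth
    #: optional separate well depth for inter-chain native pairs; None
    #: uses `epsilon`.  Toy studies deepen the interfacial wells so the
    #: binding and folding transitions are comparable, as for real
    #: 3-state homodimers.
    epsilon_inter: float | None = None
    sigma_nc: float = 0.4       # excluded-volume radius, nm
    epsilon_rep: float = 1.0    # excluded-volume prefactor
    #: excluded volume is truncated and shifted at min(rep_cutoff,
    #: rep_native_frac * native distance) per pair, so the native
    #: structure is an exact stationary point of the potential
    rep_cutoff: float = 0.8
    rep_native_frac: float = 0.95


@dataclass(frozen=True)
class Restraint:
    """One-sided harmonic COM confinement: flat inside r0, spring k beyond."""

    r0: float = 6.0   # nm
    k: float = 1000.0  # reduced energy per nm^2


@dataclass(frozen=True)
class SBMTopology:
    """All interaction terms of one system, plus its native geometry."""

    mode: str                      # 'flexible' | 'rigid_chains'
    n_beads: int
    chain_slices: tuple[tuple[int, int], ...]
    native_coords: np.ndarray      # (n_beads, 3) nm
    # bonded terms (empty in rigid_chains mode)
    bonds: np.ndarray              # (nb, 2) int
    bond_r0: np.ndarray
    angles: np.ndarray             # (na, 3) int
    angle_t0: np.ndarray
    dihedrals: np.ndarray          # (nd, 4) int
    dihedral_p0: np.ndarray
    # native pairs (global bead indices)
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_r0: np.ndarray
    pair_eps: np.ndarray
    pair_inter: np.ndarray         # bool
    # excluded-volume pairs, truncated-shifted at per-pair cutoff rep_rc
    rep_i: np.ndarray
    rep_j: np.ndarray
    rep_inter: np.ndarray          # bool
    rep_rc: np.ndarray             # nm
    ff: ForceField = field(default_factory=ForceField)
    restraint: Restraint | None = None

    def __post_init__(self):
        if self.mode not in ("flexible", "rigid_chains"):
            raise TopologyError(f"unknown mode {self.mode!r}")
        if np.any(self.pair_eps <= 0):
            raise TopologyError("native well depth epsilon must be positive")
        if self.mode == "rigid_chains" and (len(self.bonds) or len(self.angles)
                                            or len(self.dihedrals)):
            raise TopologyError("rigid_chains mode carries no bonded terms")

    @property
    def n_chains(self) -> int:
        return len(self.chain_slices)

    @property
    def n_inter_pairs(self) -> int:
        return int(np.sum(self.pair_inter))


def _angle(a, b, c):
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d):
    # same sign convention as the force kernel
    rij, rkj, rkl = a - b, c - b, c - d
    m = np.cross(rij, rkj)
    n = np.cross(rkj, rkl)
    y = np.dot(np.cross(m, n), rkj) / np.linalg.norm(rkj)
    x = np.dot(m, n)
    return float(np.arctan2(y, x))


def build_topology(structure: DimerStructure, cmap: ContactMap,
                   ff: ForceField | None = None,
                   mode: str = "flexible",
                   restraint: Restraint | None = None) -> SBMTopology:
    """Assemble the SBM topology for a structure and its contact map.

    ``flexible`` mode emits n-1 bonds, n-2 angles and n-3 dihedrals per
    chain plus every native pair.  ``rigid_chains`` mode retains only the
    inter-chain native pairs and inter-chain excluded volume, with
    bit-identical pair parameters.
    """
    ff = ff or ForceField()
    for ch in structure.chains:
        if len(ch) < 2:
            raise TopologyError("each chain needs at least 2 beads")
    n_per = structure.n_per_chain
    n_chains = len(structure.chains)
    coords = structure.all_coords()
    slices = tuple((c * n_per, (c + 1) * n_per) for c in range(n_chains))

    bonds, angles, dihedrals = [], [], []
    if mode == "flexible":
        for c in range(n_chains):
            off = c * n_per
            bonds += [(off + i, off + i + 1) for i in range(n_per - 1)]
            angles += [(off + i, off + i + 1, off + i + 2)
                       for i in range(n_per - 2)]
            dihedrals += [(off + i, off + i + 1, off + i + 2, off + i + 3)
                          for i in range(n_per - 3)]
    bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    angles = np.array(angles, dtype=int).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=int).reshape(-1, 4)
    bond_r0 = np.array([np.linalg.norm(coords[i] - coords[j])
                        for i, j in bonds])
    angle_t0 = np.array([_angle(coords[i], coords[j], coords[k])
                         for i, j, k in angles])
    dihedral_p0 = np.array([_dihedral(coords[i], coords[j], coords[k], coords[l])
                            for i, j, k, l in dihedrals])

    inter_mask = cmap.cls == "inter"
    keep = inter_mask if mode == "rigid_chains" else np.ones(len(cmap), dtype=bool)
    gi = cmap.chain_a * n_per + cmap.res_i
    gj = cmap.chain_b * n_per + cmap.res_j
    pair_i, pair_j = gi[keep], gj[keep]
    pair_r0 = cmap.native_distance[keep]
    pair_inter = inter_mask[keep]
    eps_inter = ff.epsilon if ff.epsilon_inter is None else ff.epsilon_inter
    pair_eps = np.where(pair_inter, eps_inter, ff.epsilon)

    # Excluded volume: all non-bonded pairs (same-chain |i-j| >= 4, any
    # inter-chain pair) that are not native contacts.
    native_set = {(int(a), int(b)) for a, b in zip(np.minimum(gi, gj),
                                                   np.maximum(gi, gj))}
    rep_i, rep_j, rep_inter = [], [], []
    for a in range(n_chains):
        for b in range(a, n_chains):
            if mode == "rigid_chains" and a == b:
                continue
            if a == b:
                ii, jj = np.triu_indices(n_per, k=4)
                ii, jj = ii + a * n_per, jj + a * n_per
            else:
                ii, jj = np.indices((n_per, n_per)).reshape(2, -1)
                ii, jj = ii + a * n_per, jj + b * n_per
            for i, j in zip(ii.tolist(), jj.tolist()):
                if (min(i, j), max(i, j)) in native_set:
                    continue
                rep_i.append(i)
                rep_j.append(j)
                rep_inter.append(a != b)
    rep_i = np.array(rep_i, dtype=int)
    rep_j = np.array(rep_j, dtype=int)
    if len(rep_i):
        d_nat = np.linalg.norm(coords[rep_i] - coords[rep_j], axis=1)
        rep_rc = np.minimum(ff.rep_cutoff, ff.rep_native_frac * d_nat)
    else:
        rep_rc = np.empty(0)

    return SBMTopology(
        mode=mode, n_beads=n_per * n_chains, chain_slices=slices,
        native_coords=coords,
        bonds=bonds, bond_r0=bond_r0,
        angles=angles, angle_t0=angle_t0,
        dihedrals=dihedrals, dihedral_p0=dihedral_p0,
        pair_i=pair_i, pair_j=pair_j, pair_r0=pair_r0,
        pair_eps=pair_eps, pair_inter=pair_inter,
        rep_i=rep_i, rep_j=rep_j,
        rep_inter=np.array(rep_inter, dtype=bool), rep_rc=rep_rc,
        ff=ff, restraint=restraint,
    )
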