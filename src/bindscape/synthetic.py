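"""Synthetic toy homodimers and synthetic densities of states.

``make_toy_homodimer`` builds a two-chain bead dimer with *exactly* the
requested interfacial flexibility rho, so every pipeline stage can be
exercised without external structure data.  Each chain is a perturbed
cubic-lattice serpentine fold; the binding interface is a straight ladder
of residue pairs along one edge row, and the second chain is the first
rotated by 180 degrees about the interface axis (a proper rotation: the
two chains are identical, as in a C2 homodimer).  Interface residues that
sit on the folded core carry both inter- and intra-chain native contacts
(they count toward rho); residues on a short protruding tail carry
inter-chain contacts only.  Choosing how many ladder rungs sit on the core
therefore dials rho constructively, not approximately.

``make_discrete_dos`` inverts the topography measures: it returns a
density of states whose gap, roughness and entropy equal the requested
targets exactly (one native state at E = 0, a two-level non-native
spectrum at dE +/- DE with total count e^S), which is the oracle for the
WHAM and topography tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConstructionError
from .structures import (Chain, ContactMap, DimerStructure,
                         interfacial_flexibility)
from .wham import DensityOfStates

LATTICE = 0.5        # nm, lattice constant
ZIGZAG = 0.15        # nm, out-of-plane alternation: no colinear bead triples
INTERFACE_GAP = 0.6  # nm, nominal ladder-contact separation
CUTOFF = 0.8         # nm, must match the default contact cutoff
MIN_SEQ_SEP = 4


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one toy homodimer."""

    n_residues: int = 20        # per chain
    n_inter: int = 6            # inter-chain ladder contacts
    rho: float = 0.15           # target interfacial flexibility
    n_intra: int | None = None  # intra contacts per chain (None = all)
    seed: int = 0
    jitter: float = 0.01        # nm, lattice perturbation


@dataclass(frozen=True)
class ToyDimer:
    structure: DimerStructure
    cmap: ContactMap
    no_binding: bool = False

    def __iter__(self):
        return iter((self.structure, self.cmap))


def _serpentine(n_core: int, rows: int):
    """Lattice path (x, y) in units of LATTICE; returns coords and width."""
    W = int(np.ceil(n_core / rows))
    xy = np.empty((n_core, 2))
    for i in range(n_core):
        r, c = divmod(i, W)
        x = c if r % 2 == 0 else W - 1 - c
        xy[i] = (x, r)
    return xy, W


def _intra_candidates(coords: np.ndarray, core_idx: np.ndarray):
    """Same-chain candidate contacts among core beads (sep >= 4, r <= cutoff)."""
    cand = []
    for ai, i in enumerate(core_idx):
        for j in core_idx[ai + 1:]:
            if j - i < MIN_SEQ_SEP:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= CUTOFF:
                cand.append((int(i), int(j)))
    return cand


def make_toy_homodimer(spec: ToySpec) -> ToyDimer:
    """Build a toy homodimer with interfacial_flexibility == spec.rho exactly.

    All interfacial rungs sit on the fold's edge row, so the interface
    geometry is identical for every rho: the coupling is dialed purely in
    the contact map, by deleting the intra-chain contacts of the
    inter-only rungs.  This mirrors real interfaces, where residues
    binding without folding contacts still belong to the ordered surface.
    """
    n = spec.n_residues
    if n < 6:
        raise ConstructionError("need at least 6 residues per chain")
    b_float = spec.rho * n
    b = int(round(b_float))
    if abs(b_float - b) > 1e-9:
        raise ConstructionError(
            f"rho={spec.rho} is not representable with {n} residues; "
            f"feasible values are k/{n} for integer k")
    if b > spec.n_inter:
        raise ConstructionError(
            f"rho={spec.rho} needs {b} coupled interface residues but only "
            f"{spec.n_inter} inter contacts were requested; feasible rho "
            f"range is 0 to {spec.n_inter / n:.3g}")

    chosen = eligible = None
    for rows in (3, 2):
        xy, W = _serpentine(n, rows)
        coords = np.zeros((n, 3))
        coords[:, 0] = xy[:, 0] * LATTICE
        coords[:, 1] = xy[:, 1] * LATTICE
        coords[:, 2] = ZIGZAG * (np.arange(n) % 2)
        last_row = int(xy[-1, 1])
        row_beads = [i for i in range(n) if int(xy[i, 1]) == last_row]
        if spec.n_inter > len(row_beads):
            continue  # edge row too short; retry with a wider fold
        rungs = row_beads[len(row_beads) - spec.n_inter:]
        rng = np.random.default_rng(spec.seed)
        jit = rng.normal(0.0, spec.jitter, size=(n, 3))
        pert = coords + jit
        cand = _intra_candidates(pert, np.arange(n))
        # a rung can be "coupled" if it holds a folding contact to a
        # partner outside the interface row
        rung_set = set(rungs)
        eligible = [r for r in rungs
                    if any(r in p and not (set(p) - {r}) <= rung_set
                           for p in cand)]
        if b <= len(eligible):
            chosen = sorted(eligible[len(eligible) - b:]) if b else []
            break
    if chosen is None:
        feas = len(eligible) / n if eligible is not None else 0.0
        raise ConstructionError(
            f"rho={spec.rho} with {spec.n_inter} inter contacts is "
            f"infeasible for {n} residues; feasible rho range is 0 to "
            f"{feas:.3g} (or request fewer inter contacts)")

    interface = sorted(rungs)
    inter_only = rung_set - set(chosen)
    y_c = last_row * LATTICE
    # ladder rungs land at gap +/- zigzag depending on bead parity
    z_c = 0.5 * (INTERFACE_GAP + ZIGZAG)
    # chain B: proper C2 rotation about the x-axis through (y_c, z_c)
    other = pert.copy()
    other[:, 1] = 2.0 * y_c - pert[:, 1]
    other[:, 2] = 2.0 * z_c - pert[:, 2]

    # intra pairs: drop every candidate touching an inter-only rung, so
    # exactly the chosen rungs carry both contact kinds
    cand_sorted = sorted(p for p in cand if not (set(p) & inter_only))
    if spec.n_intra is None:
        intra = cand_sorted
    else:
        if spec.n_intra > len(cand_sorted):
            raise ConstructionError(
                f"requested {spec.n_intra} intra contacts but only "
                f"{len(cand_sorted)} exist; feasible range is "
                f"{b} to {len(cand_sorted)}")
        if spec.n_intra < b:
            raise ConstructionError(
                f"need at least {b} intra contacts to cover the {b} "
                "coupled interface residues")
        intra, used = [], set()
        for r in chosen:  # one covering pair per coupled residue
            pr = min(p for p in cand_sorted if r in p)
            if pr not in used:
                intra.append(pr)
                used.add(pr)
        for pr in cand_sorted:
            if len(intra) >= spec.n_intra:
                break
            if pr not in used:
                intra.append(pr)
                used.add(pr)
        intra = sorted(intra)

    ca, ri, cb, rj, dist, cls = [], [], [], [], [], []
    for c, xyz in ((0, pert), (1, other)):
        for i, j in intra:
            ca.append(c); ri.append(i); cb.append(c); rj.append(j)
            dist.append(float(np.linalg.norm(xyz[i] - xyz[j])))
            cls.append("intra")
    for r in interface:
        ca.append(0); ri.append(r); cb.append(1); rj.append(r)
        dist.append(float(np.linalg.norm(pert[r] - other[r])))
        cls.append("inter")

    chain_a = Chain("A", np.arange(1, n + 1), pert)
    chain_b = Chain("B", np.arange(1, n + 1), other)
    structure = DimerStructure(chains=(chain_a, chain_b), box_size=12.0)
    cmap = ContactMap(np.array(ca, int), np.array(ri, int), np.array(cb, int),
                      np.array(rj, int), np.array(dist), np.array(cls, "<U5"),
                      n_per_chain=n, n_chains=2)
    flex = interfacial_flexibility(cmap)
    if abs(flex.rho - spec.rho) > 1e-12:
        raise ConstructionError(
            f"internal inconsistency: built rho={flex.rho}, requested "
            f"{spec.rho}")
    return ToyDimer(structure=structure, cmap=cmap,
                    no_binding=spec.n_inter == 0)


def extract_monomer(dimer: DimerStructure, cmap: ContactMap):
    """Chain 0 as an isolated monomer with its intra contact map."""
    mono = dimer.monomer()
    sub = cmap.intra_of_chain(0)
    mono_map = ContactMap(sub.chain_a, sub.res_i, sub.chain_b, sub.res_j,
                          sub.native_distance, sub.cls,
                          n_per_chain=cmap.n_per_chain, n_chains=1)
    return mono, mono_map


def make_discrete_dos(target, bins: float | None = None) -> DensityOfStates:
    """Exact-moment density of states for targets (delta_E, Delta_E, S).

    One native state at E = 0; non-native states at dE - DE and dE + DE
    with e^S / 2 states each (a single level of e^S states when DE = 0).
    ``landscape_moments`` of the result under the min-energy native rule
    reproduces the targets exactly.
    """
    delta_E, Delta_E, S = target
    if delta_E < 0 or Delta_E < 0 or S < 0:
        raise ConstructionError("targets must be non-negative")
    if delta_E <= Delta_E:
        raise ConstructionError(
            "need delta_E > Delta_E so the native state stays lowest")
    if Delta_E == 0:
        levels = np.array([0.0, delta_E])
        log_counts = np.array([0.0, S])
    else:
        levels = np.array([0.0, delta_E - Delta_E, delta_E + Delta_E])
        log_counts = np.array([0.0, S - np.log(2.0), S - np.log(2.0)])
    gaps = np.diff(levels)
    h = bins if bins is not None else float(gaps.min()) / 4.0
    h = min(h, float(gaps.min()) / 2.0)
    edges, log_n = [levels[0] - h / 2.0], []
    for idx, lv in enumerate(levels):
        if edges[-1] < lv - h / 2.0 - 1e-12:
            edges.append(lv - h / 2.0)   # filler (empty) bin
            log_n.append(-np.inf)
        edges.append(lv + h / 2.0)
        log_n.append(log_counts[idx])
    return DensityOfStates(np.array(edges), np.array(log_n), None,
                           normalization="native")


def sample_energies(dos: DensityOfStates, T: float, n: int,
                    seed: int) -> np.ndarray:
    """I.i.d. canonical energy draws: P(bin) proportional to n(E) e^{-E/T}."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if n < 1:
        raise ValueError("need at least one sample")
    mdos = dos.marginal_energy()
    centers = mdos.energy_centers
    logits = mdos.log_n - centers / T
    finite = np.isfinite(logits)
    p = np.exp(logits[finite] - logits[finite].max())
    p /= p.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(centers[finite], size=n, p=p)
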