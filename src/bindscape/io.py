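"""Readers and writers for every artifact file.

All tabular artifacts are TSV with a fixed header; floats are written with
17 significant digits so every writer/reader pair round-trips bit-exactly.
Summaries and sidecars are JSON with sorted keys (byte-stable across
reruns); configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError
from .structures import Chain, ContactMap, DimerStructure
from .topology import SBMTopology
from .wham import DensityOfStates, ThermalCurve

_F = "%.17g"


def _fmt(x: float) -> str:
    return _F % x


# ---------------------------------------------------------------------------
# density of states

def write_dos(path, dos: DensityOfStates) -> None:
    """DoS TSV: header ``E_lo  E_hi  [Q]  log_n`` + normalization comment."""
    path = Path(path)
    lines = [f"# normalization={dos.normalization}"]
    if dos.is_2d:
        lines.append("E_lo\tE_hi\tQ\tlog_n")
        for i in range(dos.log_n.shape[0]):
            for j, q in enumerate(dos.q_values):
                lines.append("\t".join([_fmt(dos.energy_edges[i]),
                                        _fmt(dos.energy_edges[i + 1]),
                                        _fmt(q), _fmt(dos.log_n[i, j])]))
    else:
        lines.append("E_lo\tE_hi\tlog_n")
        for i in range(len(dos.log_n)):
            lines.append("\t".join([_fmt(dos.energy_edges[i]),
                                    _fmt(dos.energy_edges[i + 1]),
                                    _fmt(dos.log_n[i])]))
    path.write_text("\n".join(lines) + "\n")


def read_dos(path) -> DensityOfStates:
    """Read a DoS TSV; rows may be in any order (canonically sorted)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    norm = "raw"
    rows = []
    header = None
    for ln_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "normalization=" in line:
                norm = line.split("normalization=")[1].strip()
            continue
        cols = line.split("\t")
        if header is None:
            header = cols
            if header not in (["E_lo", "E_hi", "log_n"],
                              ["E_lo", "E_hi", "Q", "log_n"]):
                raise FormatError(
                    f"{path.name}:{ln_no}: bad DoS header {header!r}")
            continue
        if len(cols) != len(header):
            raise FormatError(f"{path.name}:{ln_no}: expected "
                              f"{len(header)} columns, got {len(cols)}")
        try:
            rows.append([float(c) for c in cols])
        except ValueError:
            raise FormatError(
                f"{path.name}:{ln_no}: non-numeric value") from None
    if header is None or not rows:
        raise FormatError(f"{path.name}: empty DoS file")
    arr = np.array(rows)
    has_q = len(header) == 4
    if has_q:
        order = np.lexsort((arr[:, 2], arr[:, 0]))
    else:
        order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    e_lo = np.unique(arr[:, 0])
    e_hi = np.unique(arr[:, 1])
    if len(e_lo) != len(e_hi):
        raise FormatError(f"{path.name}: inconsistent energy bins")
    edges = np.append(e_lo, e_hi[-1])
    if has_q:
        q_values = np.unique(arr[:, 2])
        if len(arr) != len(e_lo) * len(q_values):
            raise FormatError(f"{path.name}: incomplete (E, Q) grid")
        log_n = arr[:, 3].reshape(len(e_lo), len(q_values))
        return DensityOfStates(edges, log_n, q_values, norm)
    return DensityOfStates(edges, arr[:, 2], None, norm)


def dos_io(path, dos: DensityOfStates | None = None):
    """Write ``dos`` to ``path``, or read and return the DoS at ``path``."""
    if dos is None:
        return read_dos(path)
    write_dos(path, dos)
    return dos


# ---------------------------------------------------------------------------
# curves, contact maps, trajectories

def write_curve(path, curve: ThermalCurve) -> None:
    xname = "T" if curve.kind == "Cv" else "Q"
    lines = [f"# kind={curve.kind} label={curve.label}", f"{xname}\t{curve.kind}"]
    for x, y in zip(curve.x, curve.y):
        lines.append(f"{_fmt(x)}\t{_fmt(y)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path) -> ThermalCurve:
    lines = Path(path).read_text().splitlines()
    kind, label = "Cv", ""
    rows = []
    for line in lines:
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("kind="):
                    kind = tok[5:]
                elif tok.startswith("label="):
                    label = tok[6:]
            continue
        cols = line.split("\t")
        try:
            rows.append((float(cols[0]), float(cols[1])))
        except (ValueError, IndexError):
            continue
    arr = np.array(rows)
    return ThermalCurve(arr[:, 0], arr[:, 1], label=label, kind=kind)


def write_contact_map(path, cmap: ContactMap) -> None:
    lines = [f"# n_per_chain={cmap.n_per_chain} n_chains={cmap.n_chains}",
             "chain_i\tres_i\tchain_j\tres_j\tr0_nm\tclass"]
    for k in range(len(cmap)):
        lines.append("\t".join([str(cmap.chain_a[k]), str(cmap.res_i[k]),
                                str(cmap.chain_b[k]), str(cmap.res_j[k]),
                                _fmt(cmap.native_distance[k]),
                                str(cmap.cls[k])]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_map(path) -> ContactMap:
    path = Path(path)
    lines = path.read_text().splitlines()
    n_per, n_chains = 0, 2
    rows = []
    header_seen = False
    for ln_no, line in enumerate(lines, start=1):
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("n_per_chain="):
                    n_per = int(tok.split("=")[1])
                elif tok.startswith("n_chains="):
                    n_chains = int(tok.split("=")[1])
            continue
        if not line.strip():
            continue
        if not header_seen:
            if line.split("\t") != ["chain_i", "res_i", "chain_j", "res_j",
                                    "r0_nm", "class"]:
                raise FormatError(f"{path.name}:{ln_no}: bad contact-map header")
            header_seen = True
            continue
        cols = line.split("\t")
        if len(cols) != 6:
            raise FormatError(f"{path.name}:{ln_no}: expected 6 columns")
        rows.append(cols)
    if not rows:
        raise FormatError(f"{path.name}: empty contact map")
    return ContactMap(
        np.array([int(r[0]) for r in rows]),
        np.array([int(r[1]) for r in rows]),
        np.array([int(r[2]) for r in rows]),
        np.array([int(r[3]) for r in rows]),
        np.array([float(r[4]) for r in rows]),
        np.array([r[5] for r in rows], dtype="<U5"),
        n_per_chain=n_per, n_chains=n_chains)


def write_trajectory(path, traj) -> None:
    lines = [f"# T={_fmt(traj.temperature)} dt={_fmt(traj.dt)} "
             f"seed={traj.seed} sample_every={traj.sample_every}",
             "step\tE_total\tE_inter\tE_intra\tE_kin\tQb\tQf1\tQf2\tcom_nm"]
    for k in range(len(traj)):
        lines.append("\t".join(
            [str(int(traj.step[k]))] +
            [_fmt(v) for v in (traj.e_total[k], traj.e_inter[k],
                               traj.e_intra[k], traj.e_kin[k], traj.qb[k],
                               traj.qf1[k], traj.qf2[k],
                               traj.com_distance[k])]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# structures and topologies

def to_pdb(structure: DimerStructure) -> str:
    """Minimal PDB text (CA beads, nm -> angstrom) for the toy exporter."""
    out = []
    serial = 1
    for chain in structure.chains:
        for rid, xyz in zip(chain.residue_ids, chain.coords * 10.0):
            out.append(
                f"ATOM  {serial:5d}  CA  GLY {chain.chain_id}{rid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           C")
            serial += 1
        out.append("TER")
    out.append("END")
    return "\n".join(out) + "\n"


def write_pdb(path, structure: DimerStructure) -> None:
    Path(path).write_text(to_pdb(structure))


def topology_to_json(top: SBMTopology) -> str:
    def arr(a):
        return np.asarray(a).tolist()

    payload = {
        "mode": top.mode,
        "n_beads": top.n_beads,
        "chain_slices": [list(s) for s in top.chain_slices],
        "force_field": vars(top.ff).copy() if hasattr(top.ff, "__dict__")
        else {k: getattr(top.ff, k) for k in
              ("k_bond", "k_angle", "k_dihedral_1", "k_dihedral_3",
               "epsilon", "sigma_nc", "epsilon_rep")},
        "restraint": (None if top.restraint is None
                      else {"r0": top.restraint.r0, "k": top.restraint.k}),
        "bonds": arr(top.bonds), "bond_r0": arr(top.bond_r0),
        "angles": arr(top.angles), "angle_t0": arr(top.angle_t0),
        "dihedrals": arr(top.dihedrals), "dihedral_p0": arr(top.dihedral_p0),
        "pairs": {"i": arr(top.pair_i), "j": arr(top.pair_j),
                  "r0": arr(top.pair_r0), "eps": arr(top.pair_eps),
                  "inter": arr(top.pair_inter.astype(int))},
        "excluded": {"i": arr(top.rep_i), "j": arr(top.rep_j),
                     "inter": arr(top.rep_inter.astype(int))},
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def write_topology(path, top: SBMTopology) -> None:
    Path(path).write_text(topology_to_json(top))


# ---------------------------------------------------------------------------
# JSON / YAML helpers

def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
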