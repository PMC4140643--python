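"""Native geometry of coarse-grained homodimers and their contact maps.

A structure is reduced to one bead per residue at the C-alpha position
(coordinates in nm).  Native contacts are classified as *intra*-chain
(monomeric folding contacts, defining Qf) or *inter*-chain (interfacial
binding contacts, defining Qb).  The fraction of residues participating in
both kinds of contact, rho, measures interfacial flexibility: the degree to
which binding and folding are coupled at the interface.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, StructureError

#: default C-alpha contact cutoff (nm)
DEFAULT_CUTOFF = 0.8
#: default minimum |i-j| for an intra-chain contact
DEFAULT_MIN_SEQ_SEP = 4


@dataclass(frozen=True)
class Chain:
    """One bead chain: residue ids and C-alpha coordinates in nm."""

    chain_id: str
    residue_ids: np.ndarray  # (n,) int
    coords: np.ndarray  # (n, 3) float, nm

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(
            self, "residue_ids", np.asarray(self.residue_ids, dtype=int)
        )
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise StructureError("chain coordinates must be (n, 3)")
        if len(self.residue_ids) != len(coords):
            raise StructureError("residue ids and coordinates differ in length")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class DimerStructure:
    """A one- or two-chain bead structure in a cubic box.

    In dimer mode there are exactly two chains of equal length (homodimer);
    monomer mode holds a single chain.
    """

    chains: tuple[Chain, ...]
    box_size: float = 12.0

    def __post_init__(self):
        object.__setattr__(self, "chains", tuple(self.chains))
        if len(self.chains) not in (1, 2):
            raise StructureError(
                f"expected 1 (monomer) or 2 (dimer) chains, got {len(self.chains)}"
            )
        if len(self.chains) == 2 and len(self.chains[0]) != len(self.chains[1]):
            raise StructureError(
                "homodimer chains differ in length: "
                f"{len(self.chains[0])} vs {len(self.chains[1])}"
            )
        if self.box_size <= 0:
            raise StructureError("box_size must be positive")

    @property
    def is_dimer(self) -> bool:
        return len(self.chains) == 2

    @property
    def n_per_chain(self) -> int:
        return len(self.chains[0])

    @property
    def n_beads(self) -> int:
        return sum(len(c) for c in self.chains)

    def all_coords(self) -> np.ndarray:
        """Concatenated (n_beads, 3) coordinates, chain 0 first."""
        return np.concatenate([c.coords for c in self.chains], axis=0)

    def bead_index(self, chain: int, res: int) -> int:
        """Global bead index of residue ``res`` (0-based) of ``chain``."""
        return chain * self.n_per_chain + res if chain else res

    def monomer(self) -> "DimerStructure":
        """Chain 0 as an isolated monomer structure."""
        return DimerStructure(chains=(self.chains[0],), box_size=self.box_size)


@dataclass(frozen=True)
class ContactMap:
    """Native contact pairs of a structure.

    Pairs are stored as parallel arrays; residue indices are 0-based within
    their chain.  ``cls`` is ``"intra"`` or ``"inter"`` — a partition: every
    pair is exactly one of the two.
    """

    chain_a: np.ndarray  # (m,) int
    res_i: np.ndarray  # (m,) int
    chain_b: np.ndarray  # (m,) int
    res_j: np.ndarray  # (m,) int
    native_distance: np.ndarray  # (m,) float, nm
    cls: np.ndarray  # (m,) '<U5'
    n_per_chain: int = 0
    n_chains: int = 2

    def __post_init__(self):
        for name in ("chain_a", "res_i", "chain_b", "res_j"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        object.__setattr__(
            self, "native_distance", np.asarray(self.native_distance, dtype=float)
        )
        object.__setattr__(self, "cls", np.asarray(self.cls, dtype="<U5"))
        if np.any(self.native_distance <= 0):
            raise StructureError("native distances must be positive")
        if not set(np.unique(self.cls)) <= {"intra", "inter"}:
            raise StructureError("contact class must be 'intra' or 'inter'")
        # duplicate-free under canonical ordering
        key = self._keys()
        if len(np.unique(key)) != len(key):
            raise StructureError("duplicate contact pairs")

    def _keys(self) -> np.ndarray:
        a = np.minimum(self.chain_a * 10**6 + self.res_i,
                       self.chain_b * 10**6 + self.res_j)
        b = np.maximum(self.chain_a * 10**6 + self.res_i,
                       self.chain_b * 10**6 + self.res_j)
        return a * 10**12 + b

    def __len__(self) -> int:
        return len(self.res_i)

    def subset(self, which: str) -> "ContactMap":
        """Pairs of one class: ``"intra"``, ``"inter"`` or ``"all"``."""
        if which == "all":
            return self
        m = self.cls == which
        return ContactMap(self.chain_a[m], self.res_i[m], self.chain_b[m],
                          self.res_j[m], self.native_distance[m], self.cls[m],
                          self.n_per_chain, self.n_chains)

    def intra_of_chain(self, chain: int) -> "ContactMap":
        m = (self.cls == "intra") & (self.chain_a == chain)
        return ContactMap(self.chain_a[m], self.res_i[m], self.chain_b[m],
                          self.res_j[m], self.native_distance[m], self.cls[m],
                          self.n_per_chain, self.n_chains)

    @property
    def n_inter(self) -> int:
        return int(np.sum(self.cls == "inter"))

    @property
    def n_intra(self) -> int:
        return int(np.sum(self.cls == "intra"))


@dataclass(frozen=True)
class FlexibilityMeasure:
    """Interfacial flexibility rho and its residue bookkeeping.

    rho = (# residues with at least one inter AND one intra native contact)
          / (total residues).
    """

    rho: float
    n_inter_only: int
    n_intra_only: int
    n_both: int
    n_residues: int

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise StructureError("rho must lie in [0, 1]")
        if self.n_inter_only + self.n_intra_only + self.n_both > self.n_residues:
            raise StructureError("contact-class counts exceed residue count")


def read_structure(pdb_text: str, mode: str = "dimer",
                   box_size: float = 12.0) -> DimerStructure:
    """Parse PDB-format text into a C-alpha bead structure.

    One bead per residue at the CA position; PDB angstrom coordinates are
    converted to nm.  Chains are ordered by chain id.

    Parameters
    ----------
    pdb_text : PDB-format text with ATOM records containing CA atoms.
    mode : ``"dimer"`` (exactly two equal-length chains) or ``"monomer"``
        (exactly one chain).
    """
    from Bio.PDB import PDBParser

    if mode not in ("dimer", "monomer"):
        raise ValueError(f"unknown mode {mode!r}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = next(iter(parser.get_structure("x", _io.StringIO(pdb_text))))
        except StopIteration:
            raise ParseError("no model in PDB text") from None
    chains = []
    for ch in sorted(model, key=lambda c: c.id):
        rids, xyz = [], []
        for residue in ch:
            if "CA" in residue:
                rids.append(residue.id[1])
                xyz.append(residue["CA"].coord / 10.0)  # angstrom -> nm
        if rids:
            chains.append(Chain(ch.id, np.array(rids), np.array(xyz, dtype=float)))
    if not chains:
        raise ParseError("no CA atoms found in PDB text")
    want = 2 if mode == "dimer" else 1
    if len(chains) != want:
        raise StructureError(
            f"{mode} mode expects {want} chain(s) with CA atoms, got {len(chains)}"
        )
    return DimerStructure(chains=tuple(chains), box_size=box_size)


def build_contact_map(structure: DimerStructure,
                      cutoff: float = DEFAULT_CUTOFF,
                      min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> ContactMap:
    """Distance-cutoff native contact map of a structure.

    A pair (i, j) is a native contact iff its CA distance is <= ``cutoff``;
    same-chain pairs additionally require |i - j| >= ``min_seq_sep``.
    Different-chain pairs are class ``inter``, same-chain ``intra``; the
    native distance is the observed distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca, ri, cb, rj, dist, cls = [], [], [], [], [], []
    nch = len(structure.chains)
    for a in range(nch):
        ca_a = structure.chains[a].coords
        for b in range(a, nch):
            ca_b = structure.chains[b].coords
            d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=-1)
            if a == b:
                ii, jj = np.triu_indices(len(ca_a), k=min_seq_sep)
            else:
                ii, jj = np.indices((len(ca_a), len(ca_b))).reshape(2, -1)
            within = d[ii, jj] <= cutoff
            ii, jj = ii[within], jj[within]
            ca.extend([a] * len(ii))
            ri.extend(ii.tolist())
            cb.extend([b] * len(ii))
            rj.extend(jj.tolist())
            dist.extend(d[ii, jj].tolist())
            cls.extend(["intra" if a == b else "inter"] * len(ii))
    return ContactMap(np.array(ca, dtype=int), np.array(ri, dtype=int),
                      np.array(cb, dtype=int), np.array(rj, dtype=int),
                      np.array(dist, dtype=float), np.array(cls, dtype="<U5"),
                      n_per_chain=structure.n_per_chain,
                      n_chains=len(structure.chains))


def interfacial_flexibility(cmap: ContactMap) -> FlexibilityMeasure:
    """rho: fraction of residues with both inter- and intra-chain contacts."""
    if cmap.n_per_chain <= 0 or cmap.n_chains <= 0:
        raise StructureError("contact map has an empty residue universe")
    n_tot = cmap.n_per_chain * cmap.n_chains
    has_inter = np.zeros(n_tot, dtype=bool)
    has_intra = np.zeros(n_tot, dtype=bool)
    ga = cmap.chain_a * cmap.n_per_chain + cmap.res_i
    gb = cmap.chain_b * cmap.n_per_chain + cmap.res_j
    inter = cmap.cls == "inter"
    for g in (ga, gb):
        np.logical_or.at(has_inter, g[inter], True)
        np.logical_or.at(has_intra, g[~inter], True)
    n_both = int(np.sum(has_inter & has_intra))
    return FlexibilityMeasure(
        rho=n_both / n_tot,
        n_inter_only=int(np.sum(has_inter & ~has_intra)),
        n_intra_only=int(np.sum(~has_inter & has_intra)),
        n_both=n_both,
        n_residues=n_tot,
    )
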