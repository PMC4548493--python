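"""Structure data model: atoms, residues, multi-chain complexes.

Reads PDB files (first MODEL only) into a light-weight in-memory model
with hydrogens, waters and heteroatoms removed, alternate locations
resolved to the highest-occupancy conformer, and van der Waals radii
assigned per element.  Provides the cross-chain contact search every
interface operation is built on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .aminoacids import NONSTANDARD_PARENT, THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Van der Waals radii per element (A).  The default covers any element
#: not listed (mostly a safeguard; structures here are protein-only).
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW: float = 1.70

ResidueKey = tuple[str, int, str]  # (chain_id, seq_number, insertion_code)


class EmptyStructureError(ValueError):
    """Raised when a file yields no standard protein residues."""


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    coords: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa_type: str  # one-letter code, one of the 20 standard residues
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")
        if self.aa_type not in THREE_TO_ONE.values():
            raise ValueError(f"non-standard residue type {self.aa_type!r}")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class Complex:
    """A (multi-)chain protein structure; chain order follows the file."""

    identifier: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue(self, key: ResidueKey) -> Residue:
        for res in self.chains[key[0]]:
            if res.key == key:
                return res
        raise KeyError(key)

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa_type for r in self.chains[chain_id])


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by file order (stable max)
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_structure(path: str, format: str = "pdb") -> Complex:
    """Read a PDB file into a :class:`Complex`.

    Keeps polymer ATOM records of the first model; drops waters,
    heteroatoms and hydrogens; resolves altlocs to the highest-occupancy
    conformer (first in file on ties); maps common modified residues
    (e.g. MSE) to their standard parent and skips, with a warning, any
    residue that has no standard mapping.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format: {format!r}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    cx = Complex(identifier=st.name or "structure")
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            name = res.name.upper()
            if name == "HOH":
                continue
            if name in NONSTANDARD_PARENT:
                name = NONSTANDARD_PARENT[name]
            if name not in THREE_TO_ONE:
                if res.het_flag != "H":
                    logger.warning(
                        "skipping non-standard residue %s %s%d%s",
                        res.name, chain.name, res.seqid.num, res.seqid.icode.strip(),
                    )
                continue
            # group altlocs by atom name, keep the best conformer
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for aname, group in by_name.items():
                a = _pick_altloc(group)
                element = a.element.name.upper()
                atoms.append(Atom(
                    element=element,
                    name=aname,
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    vdw_radius=VDW_RADII.get(element, DEFAULT_VDW),
                ))
            if not atoms:
                continue
            residues.append(Residue(
                chain_id=chain.name,
                seq_number=res.seqid.num,
                insertion_code=res.seqid.icode.strip(),
                aa_type=THREE_TO_ONE[name],
                atoms=tuple(atoms),
            ))
        if residues:
            cx.chains.setdefault(chain.name, []).extend(residues)

    if not cx.chains:
        raise EmptyStructureError(f"{path}: no standard protein residues")
    keys = [r.key for r in cx.residues]
    if len(keys) != len(set(keys)):
        raise ValueError(f"{path}: duplicate residue identifiers")
    return cx


def extract_chains(complex: Complex, chain_ids: set[str] | frozenset[str]) -> Complex:
    """Sub-complex restricted to ``chain_ids``; atoms unchanged."""
    missing = set(chain_ids) - set(complex.chains)
    if missing:
        raise KeyError(f"unknown chain(s): {sorted(missing)}")
    return Complex(
        identifier=complex.identifier,
        chains={c: list(complex.chains[c]) for c in complex.chains if c in chain_ids},
    )


def extract_monomer(complex: Complex, chain_id: str) -> Complex:
    """Single-chain sub-complex (the unbound reference state)."""
    return extract_chains(complex, {chain_id})


def _atom_array(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    """Flatten residues to (coords[n,3], residue_index[n])."""
    coords = []
    owner = []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            coords.append(atom.coords)
            owner.append(i)
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def residue_pairs_within(
    complex: Complex,
    chains_a: set[str],
    chains_b: set[str],
    cutoff: float,
) -> set[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs across the two chain groups with any inter-atomic
    distance ``<= cutoff`` (inclusive, in A).

    Uses a k-d tree over group B; equivalent to the brute-force scan
    over all atom pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if chains_a & chains_b:
        raise ValueError(f"chain groups overlap: {sorted(chains_a & chains_b)}")
    res_a = [r for c in complex.chains for r in complex.chains[c] if c in chains_a]
    res_b = [r for c in complex.chains for r in complex.chains[c] if c in chains_b]
    if not res_a or not res_b:
        return set()
    xyz_a, own_a = _atom_array(res_a)
    xyz_b, own_b = _atom_array(res_b)
    tree = cKDTree(xyz_b)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    neighbors = tree.query_ball_point(xyz_a, r=cutoff)
    for ia, hits in enumerate(neighbors):
        if not hits:
            continue
        ka = res_a[own_a[ia]].key
        for ib in hits:
            pairs.add((ka, res_b[own_b[ib]].key))
    return pairs


def translate(complex: Complex, shift: tuple[float, float, float]) -> Complex:
    """Rigidly translated copy (useful for tests and synthetic data)."""
    dx, dy, dz = shift
    out = Complex(identifier=complex.identifier)
    for cid, residues in complex.chains.items():
        out.chains[cid] = [
            replace(r, atoms=tuple(
                replace(a, coords=(a.coords[0] + dx, a.coords[1] + dy, a.coords[2] + dz))
                for a in r.atoms
            ))
            for r in residues
        ]
    return out
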