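"""Shared fixtures: a tiny hand-built two-chain PDB and toy complexes."""

from __future__ import annotations

import pytest

from intersav.simulate import SimulationConfig, make_toy_complex
from intersav.structure import read_structure


def pdb_line(serial, name, alt, res, chain, num, x, y, z, occ=1.0,
             element="C", record="ATOM  ", icode=" "):
    return (
        f"{record}{serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}"
        f"{num:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


#: chain A: GLY1, ALA2 (CB in two altlocs, plus a hydrogen), MSE3;
#: chain B: GLY1 (4.9 A from A GLY1), LEU2 and SER3 far away;
#: plus a water and a ligand heteroatom that must be dropped.
DIMER_PDB_LINES = [
    pdb_line(1, "CA", " ", "GLY", "A", 1, 0.0, 0.0, 0.0),
    pdb_line(2, "CA", " ", "ALA", "A", 2, 3.8, 0.0, 0.0),
    pdb_line(3, "CB", "A", "ALA", "A", 2, 3.8, 1.5, 0.0, occ=0.6),
    pdb_line(4, "CB", "B", "ALA", "A", 2, 3.8, -1.5, 0.0, occ=0.4),
    pdb_line(5, "HB1", " ", "ALA", "A", 2, 3.8, 2.5, 0.0, element="H"),
    pdb_line(6, "CA", " ", "MSE", "A", 3, 7.6, 0.0, 0.0),
    "TER",
    pdb_line(7, "CA", " ", "GLY", "B", 1, 0.0, 0.0, 4.9),
    pdb_line(8, "CA", " ", "LEU", "B", 2, 3.8, 0.0, 30.0),
    pdb_line(9, "CA", " ", "SER", "B", 3, 7.6, 0.0, 30.0),
    "TER",
    pdb_line(10, "O", " ", "HOH", "B", 101, 20.0, 20.0, 20.0,
             element="O", record="HETATM"),
    pdb_line(11, "C1", " ", "LIG", "B", 102, 25.0, 25.0, 25.0,
             record="HETATM"),
    "END",
]


@pytest.fixture
def dimer_pdb(tmp_path):
    path = tmp_path / "dimer.pdb"
    path.write_text("\n".join(DIMER_PDB_LINES) + "\n")
    return path


@pytest.fixture
def dimer(dimer_pdb):
    return read_structure(dimer_pdb)


@pytest.fixture(scope="session")
def toy():
    """Default toy two-chain complex with its ground-truth contacts."""
    return make_toy_complex(SimulationConfig(seed=11))


def brute_force_pairs(complex, chains_a, chains_b, cutoff):
    """All-atom-pairs oracle for the neighbor search."""
    res_a = [r for c in chains_a for r in complex.chains.get(c, [])]
    res_b = [r for c in chains_b for r in complex.chains.get(c, [])]
    pairs = set()
    for ra in res_a:
        for rb in res_b:
            hit = False
            for aa in ra.atoms:
                for ab in rb.atoms:
                    d2 = sum((p - q) ** 2 for p, q in zip(aa.coords, ab.coords))
                    if d2 <= cutoff * cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                pairs.add((ra.key, rb.key))
    return pairs
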