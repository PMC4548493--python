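"""Solvent-accessible surface area by the Shrake-Rupley method.

Test points are placed on a deterministic Fibonacci (golden-spiral)
lattice on each atom's solvent-expanded sphere; a point is accessible
iff it lies outside every other atom's expanded sphere.  No random
numbers are involved, so areas are bit-stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .aminoacids import MAX_ASA
from .structure import Complex, Residue, ResidueKey, _atom_array

logger = logging.getLogger(__name__)

DEFAULT_PROBE = 1.4  # A, water
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    per_atom: np.ndarray             # A^2, flat over atoms in residue order
    per_residue: dict[ResidueKey, float]  # A^2
    probe_radius: float
    n_points: int

    def residue_area(self, key: ResidueKey) -> float:
        return self.per_residue[key]


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on a golden-spiral lattice."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5.0)) / 2
    theta = 2 * np.pi * i / phi
    z = 1 - (2 * i + 1) / n
    rho = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(
    complex: Complex,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Per-atom and per-residue SASA of every atom in ``complex``."""
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")

    residues = complex.residues
    coords, owner = _atom_array(residues)
    radii = np.array(
        [a.vdw_radius for r in residues for a in r.atoms], dtype=float
    )
    expanded = radii + probe_radius
    n_atoms = len(coords)
    unit = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_r = expanded.max()
    per_atom = np.empty(n_atoms)
    for i in range(n_atoms):
        ri = expanded[i]
        # candidate occluders: any atom whose expanded sphere can reach
        # the test sphere of atom i
        cand = tree.query_ball_point(coords[i], r=ri + max_r)
        cand = [j for j in cand if j != i]
        pts = coords[i] + ri * unit
        if cand:
            d2 = ((pts[:, None, :] - coords[cand][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[cand] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4 * np.pi * ri * ri

    per_residue: dict[ResidueKey, float] = {}
    for idx, res in enumerate(residues):
        per_residue[res.key] = float(per_atom[owner == idx].sum())
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def relative_sasa(
    sasa: SasaResult, residue: Residue, table: dict[str, float] | None = None
) -> float:
    """Residue SASA divided by its extended-tripeptide reference area.

    May exceed 1 for distorted conformations; values are not clamped
    (a warning is logged instead).
    """
    table = MAX_ASA if table is None else table
    ref = table[residue.aa_type]  # KeyError for unknown types
    frac = sasa.per_residue[residue.key] / ref
    if frac > 1.0:
        logger.debug("rSASA %.2f > 1 for %s", frac, residue.key)
    return frac


def classify_exposure(rsasa: float, cutoff: float = 0.07) -> str:
    """``"buried"`` iff rSASA is strictly below ``cutoff``, else
    ``"accessible"`` (7% relative accessibility by default)."""
    if rsasa < 0:
        raise ValueError("rSASA cannot be negative")
    return "buried" if rsasa < cutoff else "accessible"
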