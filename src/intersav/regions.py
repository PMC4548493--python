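"""Four-region anatomy of a protein complex.

Every standard residue is assigned to exactly one of:

``buried``
    relative accessibility in the *unbound* partner below the exposure
    cutoff (7% by default);
``core``
    interface residue that becomes buried on binding (bound-state rSASA
    below the cutoff);
``rim``
    interface residue that remains partially exposed in the complex;
``surface``
    accessible residue outside the interface.

The interface is the set of residues with any atom within the distance
cutoff (5 A by default) of the partner chain group.  Monomer-buried
residues keep the ``buried`` label even when they sit within the
distance cutoff of the partner: the buried/accessible split is applied
first, and only accessible residues are partitioned into core, rim and
surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import sasa as _sasa
from .params import Parameters
from .structure import Complex, ResidueKey, extract_chains, residue_pairs_within

REGIONS = ("buried", "core", "rim", "surface")


@dataclass(frozen=True)
class RegionAnnotation:
    key: ResidueKey
    aa_type: str
    sasa_monomer: float
    rsasa_monomer: float
    sasa_complex: float
    rsasa_complex: float
    is_interface: bool
    region: str

    def __post_init__(self) -> None:
        assert self.region in REGIONS
        if self.region in ("core", "rim"):
            assert self.is_interface


def find_interface(
    complex: Complex,
    chains_a: set[str],
    chains_b: set[str],
    cutoff: float = 5.0,
) -> set[ResidueKey]:
    """Residues (on either side) in any cross-group contact within ``cutoff``."""
    pairs = residue_pairs_within(complex, chains_a, chains_b, cutoff)
    keys: set[ResidueKey] = set()
    for ka, kb in pairs:
        keys.add(ka)
        keys.add(kb)
    return keys


def assign_regions(
    complex: Complex,
    chains_a: set[str],
    chains_b: set[str],
    params: Parameters | None = None,
) -> dict[ResidueKey, RegionAnnotation]:
    """Partition every residue of the complex into the four regions.

    The unbound reference for each residue is the sub-complex made of
    its own chain group, so a multi-chain binding partner is treated as
    one unit.
    """
    params = params or Parameters()
    if not chains_a or not chains_b:
        raise ValueError("both chain groups must be non-empty")

    interface = find_interface(complex, chains_a, chains_b, params.distance_cutoff)
    sasa_bound = _sasa.shrake_rupley(complex, params.probe_radius, params.n_points)

    annotations: dict[ResidueKey, RegionAnnotation] = {}
    for group in (chains_a, chains_b):
        present = group & set(complex.chains)
        if not present:
            continue
        monomer = extract_chains(complex, present)
        sasa_free = _sasa.shrake_rupley(monomer, params.probe_radius, params.n_points)
        for res in monomer.residues:
            rs_mono = _sasa.relative_sasa(sasa_free, res, params.max_asa)
            rs_bound = sasa_bound.per_residue[res.key] / params.max_asa_for(res.aa_type)
            in_iface = res.key in interface
            if rs_mono < params.exposure_cutoff:
                region = "buried"
            elif in_iface:
                region = "core" if rs_bound < params.exposure_cutoff else "rim"
            else:
                region = "surface"
            annotations[res.key] = RegionAnnotation(
                key=res.key,
                aa_type=res.aa_type,
                sasa_monomer=sasa_free.per_residue[res.key],
                rsasa_monomer=rs_mono,
                sasa_complex=sasa_bound.per_residue[res.key],
                rsasa_complex=rs_bound,
                is_interface=in_iface,
                region=region,
            )
    return annotations


def region_sizes(annotations: dict[ResidueKey, RegionAnnotation]) -> dict[str, int]:
    """Residue counts per region (keys always the four region names)."""
    if not annotations:
        raise ValueError("no annotations")
    counts = {r: 0 for r in REGIONS}
    for ann in annotations.values():
        counts[ann.region] += 1
    return counts


def annotations_frame(annotations: dict[ResidueKey, RegionAnnotation]) -> pd.DataFrame:
    """Annotations as a tidy table, one row per residue."""
    rows = [
        {
            "chain": a.key[0],
            "resnum": a.key[1],
            "icode": a.key[2],
            "aa": a.aa_type,
            "sasa_monomer": a.sasa_monomer,
            "rsasa_monomer": a.rsasa_monomer,
            "sasa_complex": a.sasa_complex,
            "rsasa_complex": a.rsasa_complex,
            "is_interface": a.is_interface,
            "region": a.region,
        }
        for a in annotations.values()
    ]
    return pd.DataFrame(rows).sort_values(["chain", "resnum", "icode"]).reset_index(drop=True)
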