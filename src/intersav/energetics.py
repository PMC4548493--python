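"""Binding free-energy tiers for alanine-scan and variant energies.

Energies come from an external predictor (e.g. an empirical force-field
alanine scan) as a TSV; this module only classifies them.

Wild-type tiers (alanine-scan contribution of the residue, kcal/mol):
``negligible`` < 0.5 <= ``minor`` < 1 <= ``warm`` < 2 <= ``hotspot``.

Variant tiers (change in binding free energy of the complex, kcal/mol):
``modest`` < 1 <= ``intermediate`` < 2 <= ``destabilizing``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .structure import ResidueKey

logger = logging.getLogger(__name__)

WT_TIERS = ("negligible", "minor", "warm", "hotspot")
MUT_TIERS = ("modest", "intermediate", "destabilizing")


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


@dataclass(frozen=True)
class EnergyRecord:
    key: ResidueKey
    ddg_wt: float
    wt_tier: str
    mut_aa: str | None = None
    ddg_mut: float | None = None
    mut_tier: str | None = None


def classify_wt_energy(
    ddg_wt: float, minor: float = 0.5, warm: float = 1.0, hotspot: float = 2.0
) -> str:
    if not math.isfinite(ddg_wt):
        raise ValueError(f"non-finite ddg_wt: {ddg_wt}")
    if ddg_wt >= hotspot:
        return "hotspot"
    if ddg_wt >= warm:
        return "warm"
    if ddg_wt >= minor:
        return "minor"
    return "negligible"


def classify_mut_energy(
    ddg_mut: float, intermediate: float = 1.0, destabilizing: float = 2.0
) -> str:
    if not math.isfinite(ddg_mut):
        raise ValueError(f"non-finite ddg_mut: {ddg_mut}")
    if ddg_mut >= destabilizing:
        return "destabilizing"
    if ddg_mut >= intermediate:
        return "intermediate"
    return "modest"


def read_ddg_table(path: str) -> dict[tuple, EnergyRecord]:
    """Read a per-residue/per-variant energy TSV.

    Required columns: ``chain``, ``resnum``, ``ddg_wt``; optional
    ``icode``, ``mut_aa``, ``ddg_mut``.  Duplicate
    (chain, resnum, icode, mut_aa) rows: last wins, with a warning.
    Returns records keyed by (chain, resnum, icode, mut_aa or None).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chain": str})
    required = {"chain", "resnum", "ddg_wt"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    if "icode" not in df.columns:
        df["icode"] = ""
    records: dict[tuple, EnergyRecord] = {}
    for i, row in df.iterrows():
        try:
            ddg_wt = float(row["ddg_wt"])
            if not math.isfinite(ddg_wt):
                raise ValueError
        except (TypeError, ValueError):
            raise SchemaError(f"{path}: non-numeric ddg_wt in row {i}") from None
        key: ResidueKey = (str(row["chain"]), int(row["resnum"]),
                           str(row["icode"]) if pd.notna(row["icode"]) else "")
        mut_aa = None
        ddg_mut = None
        mut_tier = None
        if "mut_aa" in df.columns and pd.notna(row.get("mut_aa")):
            mut_aa = str(row["mut_aa"])
        if "ddg_mut" in df.columns and pd.notna(row.get("ddg_mut")):
            try:
                ddg_mut = float(row["ddg_mut"])
            except (TypeError, ValueError):
                raise SchemaError(f"{path}: non-numeric ddg_mut in row {i}") from None
            mut_tier = classify_mut_energy(ddg_mut)
        full_key = key + (mut_aa,)
        if full_key in records:
            logger.warning("duplicate energy row for %s; keeping the last", full_key)
        records[full_key] = EnergyRecord(
            key=key,
            ddg_wt=ddg_wt,
            wt_tier=classify_wt_energy(ddg_wt),
            mut_aa=mut_aa,
            ddg_mut=ddg_mut,
            mut_tier=mut_tier,
        )
    return records
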