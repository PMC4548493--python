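"""Missense variant tables: parsing, quality filters and mapping onto
structure residues.

Variant tables follow the UniProt humsavar dialect (gene, accession,
protein change like ``p.Arg115Trp``, category disease / polymorphism /
unclassified) or a plain header-driven TSV.  Unclassified variants are
kept but flagged as not analysable.  Mapping onto a structure verifies
the wild-type residue against the structure sequence; mismatching or
uncovered variants go to side reports rather than being dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .aminoacids import STANDARD_AA, THREE_TO_ONE
from .energetics import SchemaError
from .regions import RegionAnnotation
from .structure import Complex, ResidueKey

logger = logging.getLogger(__name__)

CATEGORIES = ("disease", "polymorphism", "unclassified")

_CHANGE_RE = re.compile(r"^p\.([A-Za-z]{3})(\d+)([A-Za-z]{3})$")

# humsavar has used both wordy and abbreviated category labels
_CATEGORY_ALIASES = {
    "disease": "disease",
    "lp/p": "disease",
    "polymorphism": "polymorphism",
    "lb/b": "polymorphism",
    "unclassified": "unclassified",
    "us": "unclassified",
}


class ParseError(ValueError):
    """A protein-change string could not be decoded."""


@dataclass(frozen=True)
class SAVRecord:
    accession: str
    gene: str
    wt_aa: str       # one-letter
    position: int    # 1-based UniProt sequence position
    mut_aa: str      # one-letter
    category: str
    analysable: bool = True
    sift: float | None = None
    scores: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class StructureMapping:
    accession: str
    chain_id: str
    offset: int = 0          # structure resnum = position + offset
    identity: float = 100.0  # percent
    coverage: float = 1.0    # fraction

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be in [0, 100]")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")


@dataclass(frozen=True)
class MappedSAV:
    sav: SAVRecord
    key: ResidueKey
    region: str
    rsasa: float
    mapping: StructureMapping


@dataclass
class MappingResult:
    mapped: list[MappedSAV]
    mismatched: list[tuple[SAVRecord, str]]  # (record, structure aa found)
    unmapped: list[SAVRecord]


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Decode ``p.Pro11Leu`` into ``("P", 11, "L")``.

    Three-letter codes are validated against the 20 standard residues.
    """
    m = _CHANGE_RE.match(text.strip())
    if not m:
        raise ParseError(f"malformed protein change: {text!r}")
    wt3, pos, mut3 = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for code in (wt3, mut3):
        if code not in THREE_TO_ONE:
            raise ParseError(f"non-standard amino acid {code!r} in {text!r}")
    if pos < 1:
        raise ParseError(f"position must be >= 1 in {text!r}")
    return THREE_TO_ONE[wt3], pos, THREE_TO_ONE[mut3]


def _normalize_category(raw: str) -> str:
    cat = _CATEGORY_ALIASES.get(str(raw).strip().lower())
    if cat is None:
        raise SchemaError(f"unknown variant category: {raw!r}")
    return cat


def _make_record(gene, accession, change, category, sift=None, scores=None) -> SAVRecord | None:
    wt, pos, mut = parse_protein_change(change)
    if wt == mut:
        logger.warning("rejecting synonymous record %s %s", accession, change)
        return None
    cat = _normalize_category(category)
    return SAVRecord(
        accession=str(accession),
        gene=str(gene),
        wt_aa=wt,
        position=pos,
        mut_aa=mut,
        category=cat,
        analysable=cat != "unclassified",
        sift=sift,
        scores=scores or {},
    )


def read_sav_table(path: str, dialect: str = "plain_tsv") -> list[SAVRecord]:
    """Read a variant table.

    ``humsavar_like``: whitespace-delimited, no header, columns
    gene, accession, feature-id, change, category [, rest ignored].
    ``plain_tsv``: tab-separated with a header; required columns
    gene, accession, change, category; optional numeric ``sift`` plus
    free extra numeric score columns.
    """
    records: list[SAVRecord] = []
    if dialect == "humsavar_like":
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
        if not lines:
            raise SchemaError(f"{path}: empty variant table")
        for ln in lines:
            parts = ln.split()
            if len(parts) < 5:
                raise SchemaError(f"{path}: short row {ln.strip()!r}")
            rec = _make_record(parts[0], parts[1], parts[3], parts[4])
            if rec:
                records.append(rec)
    elif dialect == "plain_tsv":
        try:
            df = pd.read_csv(path, sep="\t", comment="#")
        except pd.errors.EmptyDataError:
            raise SchemaError(f"{path}: empty variant table") from None
        required = {"gene", "accession", "change", "category"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        extra = [c for c in df.columns if c not in required and c != "sift"]
        for _, row in df.iterrows():
            sift = float(row["sift"]) if "sift" in df.columns and pd.notna(row["sift"]) else None
            scores = {c: row[c] for c in extra if pd.notna(row[c])}
            rec = _make_record(row["gene"], row["accession"], row["change"],
                               row["category"], sift, scores)
            if rec:
                records.append(rec)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return records


def filter_mappings(
    mappings: list[StructureMapping],
    min_identity: float = 30.0,
    min_coverage: float = 0.8,
) -> list[StructureMapping]:
    """Keep mappings with identity >= ``min_identity`` percent and
    coverage >= ``min_coverage`` of the reference sequence."""
    return [m for m in mappings
            if m.identity >= min_identity and m.coverage >= min_coverage]


def map_to_structure(
    savs: list[SAVRecord],
    mapping: StructureMapping,
    complex: Complex,
    annotations: dict[ResidueKey, RegionAnnotation],
) -> MappingResult:
    """Join variants onto annotated structure residues.

    A variant maps to residue (chain, position + offset).  Variants
    whose residue is absent from the structure go to the unmapped
    report; variants whose structure residue type differs from the
    stated wild type go to the mismatch report.
    """
    if mapping.chain_id not in complex.chains:
        raise KeyError(f"chain {mapping.chain_id!r} not in structure")
    by_key = {r.key: r for r in complex.chains[mapping.chain_id]}
    result = MappingResult(mapped=[], mismatched=[], unmapped=[])
    for sav in savs:
        if sav.accession != mapping.accession:
            result.unmapped.append(sav)
            continue
        key: ResidueKey = (mapping.chain_id, sav.position + mapping.offset, "")
        res = by_key.get(key)
        if res is None or key not in annotations:
            result.unmapped.append(sav)
            continue
        if res.aa_type != sav.wt_aa:
            result.mismatched.append((sav, res.aa_type))
            continue
        ann = annotations[key]
        result.mapped.append(MappedSAV(
            sav=sav, key=key, region=ann.region,
            rsasa=ann.rsasa_complex, mapping=mapping,
        ))
    return result


def collapse_duplicates(mapped: list[MappedSAV]) -> list[MappedSAV]:
    """One record per (accession, position, mutant): duplicates from
    redundant structures collapse to the highest-identity mapping."""
    best: dict[tuple, MappedSAV] = {}
    for m in mapped:
        k = (m.sav.accession, m.sav.position, m.sav.mut_aa)
        if k not in best or m.mapping.identity > best[k].mapping.identity:
            best[k] = m
    return list(best.values())
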