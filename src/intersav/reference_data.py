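"""Reference contingency counts from a published large-scale survey of
human missense variants mapped onto protein-protein complex structures.

These counts (residue totals per structural region and observed variant
counts per category, plus the energy-class blocks over interface
residues) ship with the package as a worked dataset for the enrichment
statistics; no external download is needed to reproduce the reported
odds ratios and observed/expected comparisons.

Notes on the source tables:

* the polymorphism core-vs-rim confidence interval was printed with its
  bounds swapped; this package always reports (low, high);
* the second energy block prints an expected count of 58.40 that does
  not follow from its own marginals under the proportional-allocation
  formula (which gives 57.19); the discrepancy is documented here and
  the value is recomputed, not copied.
"""

from __future__ import annotations

from .stats import ContingencyTable

#: residue totals per structural region across the surveyed complexes
REGION_TOTALS: dict[str, int] = {
    "buried": 72467,
    "core": 13486,
    "rim": 23478,
    "surface": 141704,
}

#: observed variant counts per region and category
OBSERVED: dict[str, dict[str, int]] = {
    "disease": {"buried": 1494, "core": 215, "rim": 251, "surface": 1322},
    "polymorphism": {"buried": 362, "core": 66, "rim": 175, "surface": 1096},
}

#: energy-class blocks over interface residues carrying predicted
#: alanine-scan energies: (residue totals, observed variant counts)
ENERGY_BLOCKS: dict[str, dict[str, dict[str, int]]] = {
    "ddg_wt_ge_1": {
        "totals": {"ge_1": 366, "lt_1": 29704},
        "observed": {"ge_1": 171, "lt_1": 11569},
    },
    "ddg_wt_ge_2": {
        "totals": {"ge_2": 366, "lt_2": 29704},
        "observed": {"ge_2": 72, "lt_2": 4627},
    },
}


def region_table(category: str) -> ContingencyTable:
    """Region contingency table for ``"disease"`` or ``"polymorphism"``."""
    return ContingencyTable(
        category=category,
        totals=dict(REGION_TOTALS),
        observed=dict(OBSERVED[category]),
    )


def energy_table(block: str) -> ContingencyTable:
    """Energy-class contingency table (``"ddg_wt_ge_1"`` or
    ``"ddg_wt_ge_2"``)."""
    counts = ENERGY_BLOCKS[block]
    return ContingencyTable(
        category="disease",
        totals=dict(counts["totals"]),
        observed=dict(counts["observed"]),
    )
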