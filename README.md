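# intersav

Structural annotation and enrichment statistics for missense variants
at protein–protein interfaces.

Protein–protein interfaces are not uniform: a small **core** of residues
becomes solvent-inaccessible on binding and carries most of the binding
free energy, while the surrounding **rim** stays partially exposed.
Disease-causing single amino acid variants (SAVs) and neutral
polymorphisms distribute very differently across these regions.
`intersav` implements the full analysis pipeline behind that kind of
study, for structural bioinformaticians and variant-interpretation
pipelines:

1. **Region anatomy.** Every residue of a complex is assigned to exactly
   one of four regions from Shrake–Rupley solvent-accessible surface
   area (SASA). With rSASA = SASA / maxASA (extended Gly–X–Gly
   reference) and a 7% exposure cutoff:
   * *buried* — rSASA < 7% in the unbound chain group;
   * *interface* — any atom within 5 Å of the partner group; split into
     *core* (bound-state rSASA < 7%) and *rim* (≥ 7%);
   * *surface* — accessible, non-interacting.
2. **Variant annotation.** humsavar-dialect SAV tables
   (`p.Arg115Trp`-style changes; disease / polymorphism / unclassified)
   are parsed, quality-filtered (mapping identity ≥ 30%, coverage
   ≥ 80%), verified against the structure sequence and joined to
   regions; each substitution is scored with embedded BLOSUM62 and
   Grantham matrices, SIFT classes, physicochemical change types, and
   binding free-energy tiers from external ΔΔG tables (hot spot:
   ΔΔG_WT ≥ 2 kcal/mol).
3. **Enrichment statistics.** Per-region odds ratios
   OR_ij = (x_i/(1−x_i)) / (x_j/(1−x_j)) with x = observed/total, Woolf
   95% CIs, Pearson χ² p-values, Bonferroni correction over the six
   region pairs, observed-vs-expected χ² under proportional placement,
   per-amino-acid mutability and rank-based ROC AUC.
4. **Synthetic data.** A deterministic toy dimer with a known contact
   set, binomial variant placement with configurable per-region rates,
   and a calibrated ΔΔG generator, so the entire pipeline is testable
   offline.

## Worked example

`examples/03_enrichment_reference.py` runs the enrichment statistics on
the packaged reference counts (residue totals and observed SAVs per
region from a published large-scale survey of human protein complexes):

```
=== disease (n = 3282 variants over 251135 residues) ===
  buried   observed  1494  expected   947.05  O/E 1.58
  core     observed   215  expected   176.24  O/E 1.22
  rim      observed   251  expected   306.83  O/E 0.82
  surface  observed  1322  expected  1851.88  O/E 0.71
  OR buried vs surface   2.24 [2.07, 2.41]  p = 2.2e-104  adj = 1.3e-103
  OR core vs rim         1.50 [1.25, 1.80]  p = 1.3e-05  adj = 7.9e-05
  ...
```

Disease variants are enriched ~1.5-fold in the interface core relative
to the rim and depleted on the non-interacting surface (O/E 0.71),
whereas polymorphisms show the mirror-image pattern — the structural
signature that separates harmful from neutral substitutions.

The other examples partition a toy complex
(`01_region_partition.py`), annotate variants on it
(`02_annotate_variants.py`) and verify the generator calibration
(`04_simulation_calibration.py`). The same stages are available as a
thin CLI:

```bash
intersav simulate --seed 7 --out-dir run/
intersav annotate --structure run/toy.pdb --chains-a A --chains-b B \
    --variants run/savs.tsv --ddg run/ddg.tsv --out-dir run/
intersav enrich --annotated-savs run/annotated_savs.tsv \
    --residue-annotations run/residue_annotations.tsv --out-dir run/
```

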