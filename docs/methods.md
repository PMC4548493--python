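# Methods

## Structure model

PDB files are read through gemmi (first model only). Waters, ligands
and hydrogens are removed; alternate locations are resolved to the
highest-occupancy conformer, with file order breaking ties. A small set
of common modified residues (MSE, SEP, TPO, PTR, CSO, HYP, KCX, MLY,
PCA) is mapped to the standard parent; anything else non-standard is
skipped with a warning. Van der Waals radii are per element
(C 1.70 Å, N 1.55, O 1.52, S 1.80, default 1.70) and configurable.
Hydrogens take no part in distance or surface-area calculations: most
deposited structures lack them, and including them for the minority
would make the 5 Å contact criterion inconsistent across inputs.

Cross-chain contacts use a k-d tree over one chain group queried with
the other group's atoms; a residue pair is in contact when any
inter-atomic distance is ≤ the cutoff (inclusive — "within 5 Å" is read
as ≤ 5.0). The tree search is checked against a brute-force all-pairs
scan in the test suite and is exact, not approximate.

## Solvent accessibility

SASA is computed with the Shrake–Rupley method: `n_points` test points
per atom on a Fibonacci (golden-spiral) lattice scaled to the
solvent-expanded sphere (vdW + probe radius); a point is accessible iff
it lies outside every other atom's expanded sphere. The lattice is
deterministic, so areas are bit-stable across runs and platforms.
Defaults: probe 1.4 Å (water), 960 points per atom. At 960 points an
isolated sphere is exact to well under 1%, and total areas change by
< 1% when the density doubles; individual nearly-buried residues expose
thin slivers whose area is the least stable quantity (a few lattice
cells, ~0.1–0.5 Å² each), which is harmless here because those residues
sit far below the 7% classification threshold.

Relative SASA divides a residue's area by its reference area in an
extended Gly–X–Gly tripeptide. The embedded reference table uses the
theoretical values of Tien et al. (2013); a user table can be
substituted (`Parameters.max_asa`). Published reference tables differ
by a few percent, so absolute rSASA values — but not the qualitative
region pattern — depend on this choice. Values above 1 (distorted
conformations) are kept, not clamped.

## Region partition

The exposure rule is one consistent boundary everywhere: rSASA < 7% is
buried, ≥ 7% accessible. Each residue's unbound reference state is the
sub-complex formed by its own chain group, so a multi-chain binding
partner is treated as a unit. The partition applies the
buried/accessible dichotomy first: residues buried in the unbound group
are labelled *buried* even if they fall within 5 Å of the partner;
remaining residues in the contact set become *core* (bound rSASA < 7%)
or *rim*; everything else is *surface*. This precedence makes the four
regions an exhaustive, mutually exclusive partition. When a complex is
analysed against several partners, a residue in more than one interface
keeps its most buried bound-state label (core over rim).

## Variants

Protein changes are parsed from `p.<Three><pos><Three>` strings and
validated against the 20 standard residues. Unclassified variants are
retained but flagged not analysable. Structure mappings below 30%
sequence identity or 80% coverage are discarded. Wild-type verification
against the structure sequence is mandatory; variants failing it go to
a mismatch report and variants outside coverage to an unmapped report,
so input counts are conserved. When redundant structures map the same
variant more than once, one record per (accession, position, mutant) is
kept, from the highest-identity mapping.

## Substitution scoring

BLOSUM62 and the Grantham distance matrix are embedded as constants.
The BLOSUM62 values are tested against an independently distributed
copy; the Grantham integers are tested against a recomputation from the
published composition/polarity/volume formula, which reproduces every
printed value to ±1 rounding except Asp–Trp, where the canonical
printed table (181) deviates from the formula (191) — the printed value
is used. Classes: BLOSUM62 ≥ 0 conservative, −1 non-conservative, ≤ −2
radical; Grantham ≤ 60 conservative, > 60 non-conservative, > 100
radical; SIFT ≤ 0.10 intolerant, > 0.10 tolerant, missing stays
missing.

Physicochemical groups: polar (Q N H S T Y C M W), hydrophobic
(A I L F V P G), positive (R K), negative (D E). The change-type map
covers losses and charge swaps; transitions that *gain* a property
(e.g. polar → charged) and within-group swaps are *minor*. The source
categories name only losses and charge changes, so the gain convention
was a genuinely open choice; the map is a plain dict argument and can
be overridden per call. "Major change" means change type ≠ minor.

## Energetics

ΔΔG values are consumed from external alanine-scan / mutagenesis
predictions (kcal/mol, taken at face value). Wild-type tiers:
negligible < 0.5 ≤ minor < 1 ≤ warm < 2 ≤ hotspot. Variant tiers:
modest < 1 ≤ intermediate < 2 ≤ destabilizing. Band edges are closed on
the left, so each finite value maps to exactly one tier.

## Statistics

Odds ratios follow OR_ij = (x_i/(1−x_i))/(x_j/(1−x_j)) with x the
per-region variant probability. Confidence intervals are Woolf
(normal approximation on log OR, SE = √(1/a+1/b+1/c+1/d)); p-values are
Pearson χ² on the 2×2 table without continuity correction; both choices
reproduce the reference report's printed intervals and p-values.
Zero cells trigger the Haldane–Anscombe 0.5 correction and a flag.
Expected counts distribute the grand observed total proportionally to
region residue totals; the goodness-of-fit statistic is Σ(O−E)²/E with
df = regions − 1. Bonferroni uses m = 6 (the six region pairs per
category) by default, overridable. ROC AUC is the rank-based
Mann–Whitney estimator with half credit for ties.

One arithmetic caveat in the reference report: its disease core-vs-rim
odds ratio evaluates to 1.4992 from its own counts, which rounds to
1.50 rather than the printed 1.49; and the second energy block prints
an expected count (58.40) that does not follow from its marginals
(57.19 does). This package always reports recomputed values.

## Synthetic data

The toy complex is two jittered lattice blocks of C-alpha pseudo-atoms
(default 4×4×3 per chain, 4.0 Å spacing) whose facing layers sit 4.5 Å
apart, so the designed contact set — vertically aligned facing
residues — is provably the set of pairs within 5 Å, and the generator
refuses jitter/gap combinations that would break that guarantee or
clash the chains. The blocks produce all four regions: lattice
interiors are buried, facing layers give core and rim, the remainder is
surface. It emulates the geometry the partition needs, not protein
chemistry: no backbone connectivity, side chains, or realistic packing
density, so passing tests demonstrate the correctness of the
classification machinery, not performance on real structures.

Variant placement draws per-region counts binomially at configurable
rates; defaults are the reference survey's observed per-region rates,
so simulated tables reproduce the survey's odds-ratio structure in
expectation. The ΔΔG generator is a two-component mixture per region: a
folded normal (sd 0.4) confined below 1 kcal/mol plus a tail
1 + Exponential(τ) with weight w. Matching the two exceedance targets
is then exact and analytic: w = P(≥1), τ = 1/ln(P(≥1)/P(≥2)); defaults
are core (0.425, 0.203) and rim (0.232, 0.089). Infeasible targets
(P(≥2) ≥ P(≥1)) raise a configuration error. Variant energies are
generated as 0.7·ΔΔG_WT plus Gaussian noise (sd 0.8), giving the
positive wild-type/variant correlation real predictors show. One global
seed drives everything through deterministically spawned substreams;
equal seeds give byte-identical outputs.

Replicate experiments in the test suite use the survey-scale region
sizes (≈ 251 k residues) with 100 odds-ratio replicates and 400 null
replicates for the χ² type-I error check, and 10⁵ draws for the
exceedance calibration — sizes at which the checks are sharp yet the
whole suite runs in seconds.

## Known limitations

* SASA reference areas and probe radius are conventions; rSASA near the
  7% boundary can flip classification between conventions.
* The humsavar reader is a tolerant whitespace/TSV parser with a fixed
  column contract, not a reimplementation of the fixed-width format's
  every historical quirk.
* Transient versus permanent complexes are not distinguished; energies
  are single-predictor values without ensemble averaging.
* No mmCIF input, symmetry expansion or nucleic-acid chains.
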