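"""Annotate missense variants on a structure.

Simulates a structure-aligned variant table for the toy dimer, maps the
variants onto annotated residues, and prints each variant's region and
substitution scores.  Substitutions with negative BLOSUM62 scores or
large Grantham distances are the candidates for a deleterious effect.
"""

import pathlib
import tempfile

from intersav import (
    SimulationConfig, StructureMapping, assign_regions, make_toy_complex,
    map_to_structure, physchem_change, read_sav_table, savs_for_complex,
    score_substitution,
)

cfg = SimulationConfig(seed=11)
cx, _ = make_toy_complex(cfg)
annotations = assign_regions(cx, {"A"}, {"B"})

table = savs_for_complex(cx, cfg)
tmp = pathlib.Path(tempfile.mkdtemp()) / "savs.tsv"
table.to_csv(tmp, sep="\t", index=False)
savs = read_sav_table(tmp, "plain_tsv")

mapping = StructureMapping(accession="TOY_A", chain_id="A")
result = map_to_structure(
    [s for s in savs if s.accession == "TOY_A"], mapping, cx, annotations)
print(f"{len(result.mapped)} variants mapped, "
      f"{len(result.mismatched)} wild-type mismatches, "
      f"{len(result.unmapped)} outside coverage\n")

print("variant        region   BLOSUM62  Grantham  change type")
for m in result.mapped[:8]:
    s = score_substitution(m.sav.wt_aa, m.sav.mut_aa)
    c = physchem_change(m.sav.wt_aa, m.sav.mut_aa)
    name = f"{m.sav.wt_aa}{m.sav.position}{m.sav.mut_aa}"
    print(f"{name:12s}  {m.region:8s} {s.blosum62:4d} ({s.blosum_class[:4]})"
          f"  {s.grantham:4d} ({s.grantham_class[:4]})  {c.change_type}")
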