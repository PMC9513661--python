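"""Mitochondrial gene map: locate positions, classify substitutions under
the vertebrate mitochondrial genetic code, check the modification catalogue.

Coding substitutions are synonymous when the amino acid is preserved under
translation table 2 (where e.g. ATA codes Met, not Ile as in the standard
code); positions in tRNA/rRNA genes and the D-loop control region are
non-coding.
"""

from mtrnahet import check_known_modification_sites, load_default_annotation

ann = load_default_annotation()

for pos in (233, 12216, 14131, 15800):
    fa = ann.locate(pos)
    names = ", ".join(h[0] for h in fa.hits) or "(intergenic)"
    print(f"position {pos:>5}: {names} -> region class {fa.region_class}")

pos = 12216  # inside the protein-coding gene mt-Nd5
ref = ann.base(pos)
print(f"\nsubstitutions at {pos} (reference {ref}, mt-Nd5):")
for alt in "ACGT":
    if alt != ref:
        print(f"  {ref}>{alt}: {ann.classify_substitution(pos, alt)}")

report = check_known_modification_sites([179, 233, 729])
overlap = {p: hits for p, hits in report.items() if hits}
print(f"\nrRNA positions 179/233/729 vs known-modification catalogue: "
      f"{overlap or 'no overlap'}")
print("no overlap means these recurrent variant sites are not explained by"
      "\ncatalogued rRNA modifications.")
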