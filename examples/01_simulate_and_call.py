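"""Generate a synthetic paired oocyte-cumulus study and call mtRNA variants.

The generator plants maternal heteroplasmies shared within each mouse and
cell-type-specific modification artifacts, then draws read counts
binomially. The caller applies the standard thresholds: depth >= 100,
allele fraction >= 1%.
"""

from mtrnahet import FilterConfig, SimConfig, call_variants, load_default_annotation, simulate_study

ann = load_default_annotation()
meta, tables, truth = simulate_study(SimConfig(seed=7), ann)

print(f"study: {len(meta)} samples from {meta.mouse_id.nunique()} mice, "
      f"{len(truth.maternal)} planted maternal heteroplasmies")

filters = FilterConfig()  # min_depth=100, min_af=1%
sample = meta.sample_id.iloc[0]
calls = call_variants(tables[sample], ann.sequence, filters)
print(f"\n{sample}: {len(calls)} variant calls")
for c in calls[:5]:
    print(f"  pos {c.position:>5} {c.ref}>{c.alt}  h = {c.h:.3f} "
          f"({c.alt_count}/{c.depth} reads)")
print("... h is the heteroplasmy level: the fraction of transcripts at that"
      "\nposition carrying the alternate base.")
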