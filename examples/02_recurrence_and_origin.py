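"""Per-mouse recurrence filtering and maternal-origin classification.

A variant is kept only when detected in >= 2 samples of the same mouse
(noise suppression); it is classified maternal when found in more than one
cumulus sample of that mouse, since sharing across somatic samples implies
inheritance rather than a de novo germline event.
"""

from mtrnahet import (
    FilterConfig,
    SimConfig,
    call_variants,
    classify_origins,
    load_default_annotation,
    recovery_metrics,
    recurrent_variants,
    simulate_study,
)

ann = load_default_annotation()
meta, tables, truth = simulate_study(SimConfig(seed=7), ann)
filters = FilterConfig()

calls = []
for table in tables.values():
    calls += call_variants(table, ann.sequence, filters)
rvs = classify_origins(recurrent_variants(calls, meta, filters), meta, filters)

n_maternal = sum(rv.origin == "maternal" for rv in rvs)
n_cum_only = sum(rv.oocyte_detection == "cumulus_only" for rv in rvs)
print(f"{len(calls)} raw calls -> {len(rvs)} recurrent variants")
print(f"  maternal origin: {n_maternal} ({100 * n_maternal / len(rvs):.0f}%)")
print(f"  detected in cumulus only: {n_cum_only}")

m = recovery_metrics(rvs, truth, meta)
print(f"\nagainst the planted truth: recall {m['recall']:.3f}, "
      f"precision {m['precision']:.3f}, maternal agreement "
      f"{m['maternal_agreement']:.3f}")
print("recall/precision near 1 mean the planted heteroplasmies are recovered"
      "\nwith essentially no spurious recurrent calls at these depths.")
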