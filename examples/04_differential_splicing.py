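"""Differential splicing calls, event-type enrichment and dPSI correlation."""

import pandas as pd

from juncscope import (
    SimConfig, make_genome_annotation, simulate_counts, merge_junctions,
    build_groups, psi_table, compare_groups, event_type_enrichment, correlate_dpsi,
)
from juncscope.diff import diff_events_to_frame

truth = make_genome_annotation(SimConfig(seed=4, n_genes=8))
counts = simulate_counts(truth)
groups, _, _ = build_groups(merge_junctions(counts).values())
psi, cov = psi_table(groups, sorted(truth.samples))

events = compare_groups(psi, truth.samples, "WT", "MUT", coverage=cov,
                        min_dpsi=15, min_gap=5)
frame = diff_events_to_frame(events)
called = frame[frame["passed"]]
print(f"{len(called)}/{len(frame)} events pass |dPSI| >= 15 with between-group gap >= 5:")
print(called[["event_id", "ref_psi", "contrast_psi", "dpsi", "gap"]].round(2).to_string(index=False))

# Proportion test: are alternative-acceptor events over-represented among calls?
enr = event_type_enrichment({"Alt3": len(called), "other": 5},
                            {"Alt3": len(frame), "other": 60})
print("\nEvent-type enrichment (two-proportion test vs background):")
print(enr[["event_type", "prop_differential", "prop_background", "p_value"]].round(4).to_string(index=False))

# dPSI agreement between two cohorts simulated from the same truth
counts2 = simulate_counts(truth, seed=999)
groups2, _, _ = build_groups(merge_junctions(counts2).values())
psi2, cov2 = psi_table(groups2, sorted(truth.samples))
f2 = diff_events_to_frame(compare_groups(psi2, truth.samples, "WT", "MUT", coverage=cov2))
r = correlate_dpsi(frame.set_index("event_id")["dpsi"], f2.set_index("event_id")["dpsi"])
print("\nPearson correlation of dPSI between two replicate cohorts:")
print(r[["event_type", "n", "pearson_r"]].round(3).to_string(index=False))
print("High R indicates the same events shift in the same direction, the")
print("hallmark of a reproducible mutation-driven splicing signature.")
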