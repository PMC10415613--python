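"""Quantify percent-spliced-in (PSI) over acceptor groups.

Junctions sharing a donor form an acceptor group; PSI of each acceptor is
its relative read frequency (0-100) within the group, missing below 10
reads of group coverage.
"""

from juncscope import (
    SimConfig, make_genome_annotation, simulate_counts,
    merge_junctions, build_groups, psi_table,
)

truth = make_genome_annotation(SimConfig(seed=2, n_genes=4))
counts = simulate_counts(truth)
merged = merge_junctions(counts)
groups, donor_groups, quarantined = build_groups(merged.values())

samples = sorted(truth.samples)
psi, cov = psi_table(groups, samples, min_coverage=10)
print(f"{len(groups)} acceptor groups, {len(psi)} splice-site choices")
print(psi.round(1).to_string())
print("\nRows are acceptor-choice junctions; values are PSI per sample and sum")
print("to 100 within a group wherever the group has >=10 supporting reads.")
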