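"""Predict the ORF consequence of each simulated alternative 3'ss event.

Rules: net coding change not divisible by 3 -> frameshift; a new in-frame
stop >50 nt upstream of the last exon-exon junction -> PTC-NMD; an in-frame
stop shortening the protein by >=100 aa -> truncation; changes confined to
untranslated regions -> UTR; everything else preserves the ORF.
"""

from juncscope import SimConfig, make_genome_annotation, TranscriptModel, predict_impact

truth = make_genome_annotation(SimConfig(seed=5, n_genes=10))
print(f"{'gene':10s} {'strand':6s} {'d':>5s}  call")
for g in truth.genes:
    model = TranscriptModel(g.gene_id, g.chrom, g.strand, g.exons,
                            g.cds_start, g.cds_end, truth.genome)
    call = predict_impact(model, g.event_intron_index, g.distance)
    label = call.category + (f" ({call.mechanism})" if call.mechanism else "")
    print(f"{g.gene_id:10s} {g.strand:6s} {g.distance:+5d}  {label}")
print("\nd is the signed acceptor shift in transcript orientation; each call")
print("matches the consequence the generator planted in that gene's CDS.")
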