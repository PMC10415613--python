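# juncscope

Junction-centric discovery and quantification of alternative 3' splice
sites from spliced RNA-seq — built for the splicing phenotype of
branch-point-factor hotspot mutations (e.g. *SF3B1* K700E in CLL), where
mutant spliceosomes activate cryptic AG acceptors, typically 10–30 nt
upstream of the canonical 3' splice site.

## Who it is for

Researchers analysing cohorts or isogenic cell lines where a splicing-factor
mutation (or a splicing-modulator drug) shifts 3'ss choice, who need to go
from aligned reads (or STAR `SJ.out.tab` junction tables) to classified,
quantified, ORF-annotated alternative/cryptic 3'ss events — without
committing to a monolithic pipeline. Everything is importable from Python; a
thin `juncscope` CLI wraps the same functions.

## The model

For a splice donor *D* with acceptors *A₁…Aₖ* observed in the same intron,
per-sample usage of each acceptor is quantified as percent spliced in:

```
PSI(Aᵢ) = 100 · n(D→Aᵢ) / Σⱼ n(D→Aⱼ)
```

with `n` the junction-spanning read count; PSI is missing when the group
total is below 10 reads. Replicates are pooled by summing counts before the
ratio. Within each group the **canonical** acceptor is the most used 3'ss in
the reference samples; every other acceptor gets a signed distance *d*
(negative = upstream on the mRNA) and a category — NAGNAG (|d| ≤ 3), UpN/DoN
(|d| ≤ 50), UpF/DoF (|d| > 50). An acceptor whose usage changes by
|ΔPSI| ≥ 15 between conditions is **cryptic** if its reference PSI ≤ 5 and
**alternative** otherwise. Differential calls additionally require a
between-group replicate gap ≥ 5 (a within-group spread < 5 variant backs the
control-set definitions). Downstream modules predict ORF impact
(frameshift / PTC-NMD under the 50-nt rule / ≥100-aa truncation / UTR /
preserving) and profile 3'ss sequence features: a trainable first-order
log-odds acceptor-strength model over the 23-nt context, branch-point
candidates against a yUnAy-type consensus, polypyrimidine strength, and GC
RNA maps.

A fully deterministic simulator generates toy genomes with planted
canonical/cryptic acceptors, branch points, group-dependent usage and
explicit ORF consequences, so every stage is testable against ground truth.

## Worked example

`examples/` holds one short script per capability. For instance
`python examples/03_classify_events.py` simulates a six-gene cohort
(3 WT vs 3 MUT replicates, coverage ≈ 100) and prints:

```
       junction_id  distance category  status  ref_psi  dpsi
  chrS1:321-603(+)       -17      UpN cryptic     3.36 42.61
chrS1:1967-2245(+)       -21      UpN cryptic     1.76 57.24
chrS1:4421-4699(+)       -21      UpN cryptic     0.94 53.29
chrS1:1248-1526(-)       -21      UpN cryptic     1.18 37.94
chrS1:3402-3680(-)       -21      UpN cryptic     3.29 39.23
chrS1:5294-5573(-)       -20      UpN cryptic     1.43 36.46

Best surrogate-marker candidate: chrS1:4421-4699(+) (dPSI=53.3, reference PSI=0.94)
```

Each row is a non-canonical acceptor: an upstream-near (UpN) cryptic site,
essentially unused in the reference group (ref PSI ≤ 5) and strongly
activated in the mutant (ΔPSI = contrast − reference). The surrogate screen
keeps events with ΔPSI ≥ 50 and ranks them by lowest reference usage — the
top candidate is the most mutation-specific marker isoform.

The equivalent shell pipeline:

```bash
juncscope simulate --seed 1 --genes 8 --out sim/
juncscope extract  --bam sim/WT1.sam --sample WT1 --genome sim/genome.fa --out wt1.tsv
juncscope quantify --junctions sim/junctions.tsv --out psi.tsv
juncscope classify --junctions sim/junctions.tsv --meta sim/meta.tsv \
                   --ref-group WT --alt-group MUT --out events.tsv
juncscope diff     --psi psi.tsv --meta sim/meta.tsv --ref WT --alt MUT --out diff.tsv
juncscope impact   --events events.tsv --gtf sim/annotation.gtf --genome sim/genome.fa --out impact.tsv
```

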