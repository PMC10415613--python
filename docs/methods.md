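# Methods

## Junction model and extraction

A junction is an intron call `(chrom, start, end, strand)` with `start`/`end`
the 1-based first and last intronic base — the convention of STAR's
`SJ.out.tab` and of the `chrN:start-end(strand)` junction identifier used in
all outputs. Conversion to 0-based half-open coordinates happens only at BED
export. Extraction walks each alignment's CIGAR: `M/=/X/D` and `N` consume
reference; every `N` run is a junction, and a read supports it only when the
aligned blocks on both sides of the gap cover at least `min_anchor`
reference bases (default 8 nt — a conservative choice, configurable, since
anchor requirements differ across aligners). Multi-gap reads support each of
their junctions once. Counts use primary alignments passing the
mapping-quality cutoff (default 0; an `NH`-based unique-only mode is a
flag). Duplicate reads are not collapsed — junction-level PCR-duplicate
marking is upstream's job — and multi-mapper rescue is out of scope.

Strand comes from the aligner's `XS` attribute when present; otherwise, when
a genome is supplied, from the intron boundary dinucleotides (GT-AG, GC-AG,
AT-AC → `+`; their reverse complements → `−`); otherwise the junction is
kept with unknown strand and quarantined at grouping time (reported, never
silently dropped). Motif inference can never override an explicit `XS`.

## PSI

Acceptor groups collect junctions sharing `(chrom, strand, donor)` — one GT
donor, k AG acceptors; donor groups are the symmetric 5'ss structure.
Per sample, `PSI(choice) = 100 · count(choice) / group total`, undefined
when the total is below `min_coverage` (default 10 reads). Replicates are
pooled by summing counts before the ratio, so the pooled PSI is exactly the
count-weighted mean of replicate PSIs and the coverage filter applies to
the pooled total; this count-pooling choice (rather than averaging
per-replicate PSIs) keeps low-coverage replicates from diluting estimates
while still letting their reads count. Intron retention and exon skipping
are not quantified here; event-level PSI tables from external quantifiers
are accepted as inputs to the differential and control-set logic.

## Classification

The canonical acceptor of a group is the one with maximal pooled PSI in the
reference samples; ties break deterministically (annotated over de novo,
then smaller genomic coordinate). Signed distance of a non-canonical
acceptor is measured in transcript orientation (negative = upstream on the
mRNA; on the minus strand the genomic difference is negated). Categories:
|d| ≤ 3 → NAGNAG (tandem acceptors — the 3-nt default matches the classic
tandem-AG spacing and is configurable); |d| ≤ 50 → UpN/DoN; otherwise
UpF/DoF. The near/far boundary treats |d| = 50 as near. Status: |ΔPSI| < 15
→ unchanged; else cryptic when reference PSI ≤ `max_ref_psi` (default 5;
setting 0 demands strictly unobserved-in-reference), else alternative.
Surrogate-marker screening keeps events with ΔPSI ≥ 50 and ranks by
ascending reference PSI, so the top candidate is the site whose detection
most specifically indicates the mutation.

## Differential calls and control sets

ΔPSI is contrast minus reference on pooled replicates (count-weighted when
coverage is available; patient-style cohorts can instead average per-sample
PSIs by omitting the coverage matrix). Two range semantics are always
computed and stored: the between-group gap (min of the higher group's
replicates minus max of the lower group's) and the within-group spread
(max − min per group). Differential calls gate on |ΔPSI| ≥ 15 and gap ≥ 5;
control-set definitions use the spread variant, each where that reading is
standard. An optional cohort coverage rule requires ≥ 10 reads in a
configurable number of samples per group (e.g. 5 mutated / 20 reference).
Sample selection keeps mutated samples only at CCF ≥ 50% and drops samples
with mutations in a configurable splicing/RNA-metabolism gene blacklist;
every exclusion carries a machine-readable reason. Differential calls are
effect-size-gated and carry no multiple-testing correction; enrichment
p-values report raw and Benjamini–Hochberg values.

Control sets (on group-mean PSI): constitutive exons PSI > 95 in both
groups; alternative non-changing 10 < PSI < 90 in at least one group with
|ΔPSI| ≤ 5; cryptic exons PSI < 5 in both; retained introns ΔPSI ≥ 15 with
spread < 5; more-spliced ΔPSI ≤ −15 with spread < 5; non-changing introns
−1 < ΔPSI < 1 with 5 < PSI < 95. Event-type enrichment is a
continuity-corrected chi-square on the 2×2 type-vs-rest table; ΔPSI
agreement between datasets is Pearson's R on events with |ΔPSI| ≥ 15 in at
least one dataset (undefined below 3 pairs).

## ORF impact

An Alt3'ss event moves one intron's acceptor by d nt, inserting |d|
formerly intronic bases (d < 0) or deleting d exonic bases (d > 0). Changes
confined to untranslated regions are UTR. In CDS: net change mod 3 ≠ 0 is a
frameshift; otherwise the edited mRNA is translated from the original start
codon, and a premature stop more than 50 nt upstream of the last exon–exon
junction (the classical NMD rule; threshold configurable) is PTC-NMD, a
premature stop shortening the protein by ≥ 100 aa without NMD is a
truncation, and anything else preserves coding capability. When both the
NMD and truncation rules fire the call reports PTC-NMD and keeps both
flags. Multi-transcript genes are scored per transcript with a
most-severe-call summary. Missing CDS or sequence yields `unknown` with a
reason, never a guess.

## Sequence features

The acceptor strength score is a first-order (adjacent-position) log2-odds
model over the fixed 23-mer context (20 intronic nt ending in AG + 3 exonic
nt), trained on annotated acceptors with pseudocount 0.5 against a uniform
or user-supplied background; 0 means background-like, higher means closer
to the trained consensus. It reproduces the ranking/contrast semantics of
maximum-entropy-style scorers while staying self-contained; externally
computed tables can be plugged in through the same JSON serialization,
which round-trips bit-exactly. Branch points are adenosines 18–44 nt
upstream of the 3'ss (the classical 18–35 nt window with margin for
predictors that scan wider) scored against a yUnAy-type heptamer weight
matrix; the summary reports best score, candidate count, best-BP distance
and the polypyrimidine strength of the tract between the best branch A and
the AG (T weighted 1.0, C 0.75 — U-rich tracts are the stronger signal).
GC RNA maps profile a standardized exon|intron|exon model (50 nt exonic and
150 nt intronic flanks by default, clipped at half the intron; flank sizes
are recorded in the output), with per-set mean intron GC and the
intron-vs-downstream-exon GC differential. Set comparisons use two-sided
Mann–Whitney (exact where scipy's exact path applies, i.e. small tie-free
sets), raw medians and a pooled-SD normalized mean difference — any further
normalization for heatmap display is presentation-layer, not computed here.

## Simulator

The generator is the package's specification of its study conditions, not a
tuning surface. Each gene has 2–3 exons; the event intron (300 nt) carries
a consensus donor (GTAAGT), a planted TACTAAC branch point, a T-rich polyY
tract and a CAG acceptor, plus one cryptic AG at a signed distance drawn
uniformly from [−30, −10] (the regime characteristic of branch-point-factor
hotspot mutants; far/downstream components are configurable). Genes
alternate strands. Genes cycle through five explicitly constructed ORF
consequences — frameshift (|d| not divisible by 3), preserving (in-frame
pyrimidine-only insert), PTC-NMD (in-frame stop > 50 nt before the last
junction of a 3-exon gene), truncation (in-frame stop removing ≥ 100 aa in
a long last exon) and UTR (event intron in the 3' UTR) — and the generator
verifies every planted motif and CDS frame against the assembled genome
before returning. True cryptic usage is PSI 2 in the reference group and
+30–60 in the contrast group (equal under the null); per-sample coverage is
negative binomial (mean 100, dispersion 10 — the standard overdispersed
count law, Poisson in the large-dispersion limit) split by a binomial at
the group's true PSI. Read emission uses 50-nt anchors, optional `XS` tags,
multi-gap reads over 3-exon genes, sub-anchor distractor reads and
unspliced fillers; extraction of the emitted SAM reproduces the simulated
counts exactly. All outputs are byte-identical under a fixed seed.

What the simulator does not emulate: sequencing errors and quality strings,
expression-level structure beyond junction coverage, paired-end geometry,
alignment ambiguity, and the full sequence diversity of real acceptor
contexts. Passing tests therefore demonstrate the correctness of the
bookkeeping, thresholds and inference logic under the stated statistical
conditions — not performance on real libraries with alignment artefacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 20 genes with 3v3
replicates at mean coverage 100: 200 seeded cohorts for sensitivity and 200
for the null false-positive rate in the suite (100 + 100 in the acceptance
script), 20 seeded configs for extraction equivalence (10 in the script),
10 cohorts for feature directions (5 in the script), 5 for ORF recovery —
sizes chosen to make the binomial uncertainty on the reported rates small
relative to their thresholds while keeping a desk-scale footprint. PSI
conservation is checked on 1,000 random groups against an exact ratio
oracle; the distance taxonomy is checked exhaustively on d ∈ [−200, 200];
Mann–Whitney is checked against exhaustive permutation enumeration up to
set sizes of 8. Scoring is pure float64 arithmetic and deterministic to
1e-12 across runs; PSI normalization holds to 1e-6; ties in canonical
designation and branch-point selection break deterministically (annotated
status, then coordinate; higher score, then proximity to the 3'ss).

## Known limitations

Alt5'ss groups are built but not given a distance taxonomy; intron
retention and exon skipping enter only through external PSI tables; the
acceptor-strength model is a first-order approximation, not a full
maximum-entropy fit over all position dependencies; branch-point scoring
uses a fixed consensus PWM unless retrained; and the NMD rule is the 50-nt
heuristic, which real transcripts violate in known ways (long 3' UTRs,
last-exon PTCs that still destabilize).
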