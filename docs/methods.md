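# Methods

## The synthetic locus and library model

The simulator emulates an anchored-multiplex-PCR (AMP) *CFTR* assay on a
synthetic contig rather than hg19. The contig preserves what the analysis
depends on — 27 exons with sequential and legacy labels (6a/6b, 14a/14b,
17a/17b splits), intron/exon boundaries, a (TG)11(T)7 tract between exons 9
and 10 with fixed 12-bp flank anchors, two GSP2 primer anchors per exon plus
tract-flanking and breakpoint-targeting anchors, and a database of six named
recurrent del/dup with literature-style breakpoints — while compressing
introns to `intron_scale` (default 400 bp, ±20%) so a full pipeline run
takes about a second per sample. Coordinates are 0-based half-open
internally and 1-based only at VCF boundaries. Running on real data is a
configuration swap (FASTA, BED, primer and breakpoint tables), not a code
change; nothing in the callers assumes the synthetic geometry.

A sequenced molecule is modeled as: a GSP2-fixed end, a random
fragmentation end drawn uniformly from 120–180 bp away (the molecular
"start site"), and a random 12-mer barcode stored in the `RX` tag and in
the read name (so FASTQ-only workflows retain it). Unique molecules per
GSP2 anchor per haplotype copy are Poisson with mean set by
`target_unique_fragments` (default 24,000, which clears the sample QC gate
of 20,000 with the margin a passing clinical library would have); each
molecule yields 1 + Poisson(0.3) PCR copies with independent per-base
substitution errors (default rate 0.002). Two haplotypes carry the planted
genotype: heterozygous variants therefore land at expected allele fraction
0.5, and a single-copy deletion removes the affected GSP2 anchors from one
haplotype, halving expected unique coverage there. Tandem duplications
duplicate their anchors on one haplotype (expected ratio 1.5).

Reads are emitted with exact alignments derived from the haplotype edit
map. Small edits (SNVs, indels, tract replacements) appear as M/I/D CIGAR
ops. Structural edits (≥ 50 bp) are rendered the way a breakpoint-unaware
aligner would: the read aligns on the side carrying most of its bases and
is soft-clipped across the junction, so its sequence still contains the
novel junction (which the SV caller detects) while SNV/indel pileups never
see an exon-scale indel op.

What the simulator does **not** emulate: quality-score models and
context-dependent errors, PCR chimeras, polymerase errors in the original
molecule (errors are per-read, so barcode consensus removes them), index
hopping, and mapping ambiguity from genomic repeats. Passing tests
therefore demonstrate the correctness of the decision logic and the
statistics under the stated noise model — not robustness to alignment
artifacts on real genomes, which the confirmation tiers (orthogonal assays,
qPCR) exist to absorb.

## Deduplication and QC

Molecules are keyed by (barcode, start site, strand, GSP2); the consensus
is a per-column majority vote over reads sharing the modal alignment, with
ties resolved to the reference base. Reads without a barcode are dropped
with a warning and counted. Sample-level QC passes iff unique fragment
total ≥ 20,000 **and** average unique start sites per GSP2 ≥ 30, both
inclusive. Coverage uniformity is the percentage of ROI bases at or above
"mean − 20%", read as 0.8 × mean (relative, hence scale-free); sub-10×
runs are reported as maximal intervals and flagged for orthogonal
sequencing rather than failing the sample.

## Variant-level QC and the two genotyping tiers

Both tiers share one evidence engine over deduplicated fragments: AO
(supporting fragments), UAO (distinct start sites among them), DP (fragment
depth at the site), AF = AO/DP, with all comparison on left-aligned,
parsimonious variant representations. A variant is reported when AO ≥ 5,
UAO ≥ 3, AF ≥ 0.2; the 0.3 AF floor the assay shipped with remains
available (`LEGACY_FILTERS`) and a filtered call is emitted as an explicit
reference call carrying the failed criteria, so the policy change is
reproducible. Zygosity uses AF ≥ 0.8 for homozygous alternate
(conventional; configurable), and DP < 10 is a no-call, matching the 10×
threshold at which regions reflex to Sanger.

Clustered indels are the known failure mode of alignment-based counting: a
read carrying one allele of a compound heterozygote can mismatch the
other's representation and lose support. Every candidate that has support
(AO ≥ 3) but fails a filter is therefore re-counted against its local
candidate haplotype — fragments whose consensus contains the alt allele
with 10 bp of reference context on each side support the candidate
regardless of how their alignment spelled it — and the larger count wins.
The re-count is gated to supported-but-failing candidates so the thousands
of singleton error candidates in a typical sample do not trigger it.

Tier merging unions alternate calls with provenance (tier2/tier3/both);
genotype disagreements keep both candidates on the record. Every reportable
variant carries `needs_confirmation=true` — screening policy (orthogonal
confirmation precedes reporting), not doubt about the call.

## polyTG/T diplotyping

All (TG)m(T)n motifs for TG 4–14 and T 1–13 (143 haplotypes; the original
T 2–10 space of 99 is selectable) are matched exactly, anchored by both
flanks, against reads that fully span the tract — from FASTQ in either
orientation, or from alignments pre-filtered to the tract interval; the two
modes agree on error-free data. With r = count₂/count₁ of the two most
frequent haplotypes: r ≥ 0.25 heterozygous, r < 0.10 homozygous, and the
band between is **borderline**, reflexing to the orthogonal repeat assay.
The band edges are this package's decision (the category exists in
screening practice; its cutoffs are not standardized): 0.25 tolerates
allele-sampling noise at realistic spanning depths while 0.10 still
separates stutter-like stray counts from a true minor allele. A minimum of
20 spanning reads (≈10 per allele) is required; below it the result is
"insufficient". Diplotypes report in canonical order (by T length, then TG
length) in legacy nomenclature, e.g. `5T-12TG/7T-11TG`.

## Del/dup calling

**SV path.** Each database event defines a junction k-mer (12 bp each side
of the novel adjacency; for tandem duplications, copy-end abutting
copy-start). A call requires junction-containing fragments from ≥ 3
distinct start sites — paralleling UAO ≥ 3, since the paper-level setting
is not public. Events without a database breakpoint are never emitted here.

**CNV path.** Per-GSP2 unique-fragment counts are normalized by library
size (total-count division — the simplest defensible reading of "coverage
relative to a set of normal samples"), divided by the normals' per-GSP2
median, and tested with a one-sample z of the log2 ratio against the
normals' log2-ratio spread (floored at 0.05 log2 units to guard degenerate
noise-free panels). A GSP2 is flagged at ratio ≤ 0.6 or ≥ 1.3 with p ≤ 0.05
— deliberately applied raw, with no multiple-testing correction, matching
the assay's configured thresholds. Adjacent flagged GSP2s (bridging at most
one unflagged anchor) merge into a single exon-labelled call; single-GSP2
events are reported only as low-confidence, reflecting that CNV breakpoints
are imprecise at this resolution. An exclusion list removes recurrent-
artifact GSP2s from CNV calling entirely (the mechanism behind disabling
artifact-prone exon 20 (17b) primers). The z-test presumes the sample is at
panel-comparable depth — one more reason the sample QC gate precedes CNV
calling.

`combine` unions the paths; overlapping same-type calls merge with
evidence `both`, keeping the breakpoint-precise SV interval. All calls stay
unvalidated until qPCR reconciliation.

## qPCR copy number

ΔCt = Ct(target) − Ct(control) per sample; ΔΔCt subtracts the median
calibrator ΔCt; RQ = 2^−ΔΔCt (assuming ~100% efficiency, as the method
does). Triplicates are summarized by mean after dropping any replicate
> 0.5 Ct from the replicate median; fewer than two usable replicates flags
a retest. NTC amplification below Ct 35 invalidates the run. Default RQ
ranges — 0 copies < 0.2, 1 copy 0.35–0.65, 2 copies 0.8–1.2, 3 copies
1.3–1.7, anything else equivocal-with-retest — are this package's
conservative defaults (the validated clinical ranges live in assay
documentation, not the open literature) and are fully config-driven, with
overlap validation. Reconciliation validates an NGS call iff every tested
exon in its span is copy-consistent with the event type; an inconsistent
exon drops it as a false positive, an equivocal one pends retest, and no
coverage at all marks it unconfirmable.

## Triage

Percentiles use nearest-rank on the empirical distribution (reproducible
and tie-stable); ties at the cutoff are flagged. The simulated IRT
population is lognormal with median 21.5 ng/mL and log-sd 0.548, chosen so
the daily 95th percentile sits near 53 ng/mL and the 10-day 99.9th near
117 ng/mL — the scale on which the gate operates. Actionable
classifications are {CF-causing, P, LP, VCC, VOUS}; unknown labels raise,
forcing curation. Two variants count as two even if potentially in cis
(phase is unknown at screening; referral resolves it), and a 5T allele
counts toward the total when R117H is present (`count_5t_with_r117h`,
default on). VHIRT routing runs tier 2 on all top-5% infants and adds
tier 3 for VHIRT infants with zero panel variants.

## Validation studies at desk scale

The accuracy study simulates 50 samples with 0–2 panel and 0–1 off-panel
variants (error 0.002, default depth, planted variants ≥ 25 bp apart so
alleles do not collide) and pools merged-genotype confusion counts against
truth; specificity uses ROI bases as the negative universe. The
reproducibility study runs six genotype profiles × 3 replicates with fresh
seeds and barcode pools and scores pairwise equality of the full reportable
signature (merged variant genotypes + polyTG/T diplotype + status). These
sizes keep the full suite around a minute while leaving binomial
allele-fraction noise nowhere near the filter boundaries (a het at DP ≈ 400
fails AF ≥ 0.2 with probability < 10⁻³⁰). The polyTG/T tract is masked from
SNV/indel discovery (±12 bp); the dedicated repeat caller owns it, as
repeat-length alleles are not meaningfully representable as normalized
indel calls.

## Known limitations

Single-contig, diploid, germline-only; no mosaic or multi-sample calling.
SV detection is database-bound by design — novel breakpoints are only
reachable through the CNV path at exon resolution. The CNV statistic is an
open re-specification of a proprietary algorithm: equivalence is claimed at
the level of the validation's confusion structure, not per-call identity.
ACMG-style evidence evaluation is out of scope; classifications are
consumed from the panel or a lookup. Real-data GSP2 assignment uses the
nearest same-strand anchor when no tag is present, which can misassign
reads between overlapping primers.
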