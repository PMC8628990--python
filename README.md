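# tierseq

Tiered targeted-NGS analysis for cystic fibrosis newborn screening, from
molecular-barcoded reads to a per-infant screening outcome — with a
synthetic-data simulator standing in for the wet lab so the entire pipeline
is testable on a laptop.

Newborn screening for CF starts from immunoreactive trypsinogen (IRT)
measured on dried blood spots. Infants in the daily top 5% of IRT reflex to
molecular analysis of the *CFTR* gene from an anchored-multiplex-PCR (AMP)
library: every fragment is anchored at a gene-specific primer (GSP2) and
carries a molecular barcode (MBC), enabling deduplication and molecular
counting. Analysis is tiered:

1. **First tier** — IRT percentile gate: daily top 5% reflex to sequencing;
   ultra-high IRT (VHIRT, top 0.1% over a trailing 10-day window) routes to
   full analysis even with no panel variants.
2. **Second tier** — genotypes at a fixed panel of 338 clinically relevant
   variants defined by a targeted-mutation file (TMF, VCF format); off-panel
   variants are never unblinded at this tier. A variant is reported when
   AO ≥ 5, UAO ≥ 3 and AF ≥ 0.2, where AO counts supporting deduplicated
   fragments, UAO the distinct molecular start sites among them, and
   AF = AO/DP.
3. **Third tier** (VHIRT with no panel variants) — full-region SNV/indel
   discovery with the same variant-level QC; polyTG/T repeat diplotyping
   from tract-spanning reads; and del/dup detection by two complementary
   paths: breakpoint-targeted SV calling (junction-supporting reads against
   a literature breakpoint database) and panel-of-normals CNV calling
   (per-GSP2 copy ratio ≤ 0.6 or ≥ 1.3 with z-test p ≤ 0.05). NGS del/dup
   calls are confirmed by exon-targeted qPCR using relative quantitation,
   RQ = 2^−ΔΔCt with the median calibrator ΔCt as reference.

Outcomes follow the screening algorithm: ≥ 2 actionable confirmed variants →
screen-positive referral; exactly 1 → carrier letter; 0 → screen negative
(recorded as VHIRT-negative when a VHIRT infant clears full third-tier
analysis).

## Worked example

Everything below is generated — no reference download, no sequencer. The
synthetic contig has all 27 exons (with legacy labels such as 17b), a
(TG)11(T)7 tract in intron 9, GSP2 anchors, and a breakpoint database;
introns are compressed so whole-pipeline runs take seconds.

```bash
tierseq sim ref --seed 1 --out-dir ref
# reference CFTR_syn1: 14348 bp, 27 exons, 70 GSP2s, panel 338 entries -> ref

tierseq sim sample --ref-seed 1 --seed 11 --sample-id DEMO \
    --panel-variant F508del --diplotype 12:5,11:7 --out-prefix DEMO
# 30772 reads -> DEMO.sam/.fastq

tierseq qc --sam DEMO.sam --ref-seed 1 --out qc.json
# QC PASS
```

`qc.json` shows the sample clearing both gates (unique fragment total
≥ 20,000 and average unique start sites per GSP2 ≥ 30):

```json
{
  "unique_fragment_total": 23763,
  "avg_unique_start_sites_per_gsp2": 60.83,
  "deduplicated_mean_coverage": 588.33,
  "qc_pass": true,
  "uniformity_pct": 69.22,
  "low_coverage_regions": []
}
```

Second-tier genotyping reports exactly one variant among the 338 panel
sites — the planted F508del analog, heterozygous at AF 0.50:

```bash
tierseq tier2 --sam DEMO.sam --ref-seed 1 --out tier2.vcf
# 338 panel sites, 1 variant(s) -> tier2.vcf
# CFTR_syn1  5575  TGCG  T  PASS  GT:DP:AO:UAO  0/1:445:224:82
```

The polyTG/T caller counts tract-spanning reads per haplotype motif and
calls the diplotype from the top-two ratio (note the single stray count from
a sequencing-error read, which the ratio logic ignores):

```bash
tierseq polytgt --fastq DEMO.fastq --ref-seed 1 --out poly.json
# called: 5T-12TG/7T-11TG (860 spanning reads)
```

```json
{
  "counts": {"5T-12TG": 410, "7T-11TG": 395, "3T-13TG": 1},
  "total_spanning": 860,
  "diplotype": "5T-12TG/7T-11TG",
  "status": "called"
}
```

Other subcommands: `tierseq tier3-snv` (full-region discovery, VCF),
`tierseq tier3-deldup` (combined SV+CNV calls, exon nomenclature TSV),
`tierseq sim normals` / `tierseq sim qpcr` / `tierseq qpcr` (confirmatory
copy number), `tierseq compare` (callset concordance), and `tierseq screen`
(IRT gate plus tier routing from a manifest).

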