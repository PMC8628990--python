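"""Third-tier full-region SNV/indel discovery, callset comparison, and
tier merging.

``call_region`` discovers variants across the whole region of interest from
the fragment pileup, applying the same AO/UAO/AF variant-level QC as the
second tier. Every candidate is additionally re-evaluated against reads
matched to the candidate haplotype (see
:meth:`tierseq.pileup.FragmentPileup.kmer_recount`), so clustered indels —
e.g. compound-heterozygous adjacent deletions where one allele's reads carry
mismatches relative to the other's alignment — cannot suppress a passing
allele. The polyTG/T tract is masked here; the dedicated repeat caller owns
it.

``compare_callsets`` is the concordance engine (vcfeval-style, after
normalization); ``merge_tiers`` unions second- and third-tier calls with
per-variant provenance, flagging everything for orthogonal confirmation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pysam

from .pileup import FragmentPileup
from .variants import Variant, VariantCall, VariantFilters


@dataclasses.dataclass
class Callset:
    sample_id: str
    calls: list[VariantCall]
    roi: list[tuple[int, int]]
    caller_id: str


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def call_region(
    fragments,
    roi: list[tuple[int, int]],
    ref_seq: str,
    *,
    filters: VariantFilters = VariantFilters(),
    mask: list[tuple[int, int]] = (),
    sample_id: str = "sample",
    caller_id: str = "tier3-snv",
    pileup: FragmentPileup | None = None,
) -> Callset:
    """Discover SNVs/indels over the ROI from deduplicated fragments."""
    if pileup is None:
        pileup = FragmentPileup(fragments, ref_seq)
    calls: list[VariantCall] = []
    for v in sorted(pileup.candidates):
        if not _in_intervals(v.pos, roi) or _in_intervals(v.pos, mask):
            continue
        dp = pileup.depth_at(v.pos)
        if dp < filters.min_dp:
            continue
        ev = pileup.evidence_for(v, use_kmer=False)
        passes = (ev.ao >= filters.min_ao and ev.uao >= filters.min_uao
                  and ev.ao / dp >= filters.min_af)
        if not passes and ev.ao >= filters.min_uao:
            # candidate-haplotype re-evaluation: clustered indels must not
            # suppress a passing allele through alignment representation
            ev2 = pileup.evidence_for(v, use_kmer=True)
            if ev2.ao > ev.ao:
                ev = ev2
        ao = min(ev.ao, dp)
        af = ao / dp
        if ao >= filters.min_ao and ev.uao >= filters.min_uao and af >= filters.min_af:
            genotype = "alt/alt" if af >= filters.hom_af else "ref/alt"
            calls.append(VariantCall(site=v, genotype=genotype, DP=dp, AO=ao,
                                     UAO=min(ev.uao, ao), AF=af))
    return Callset(sample_id=sample_id, calls=calls, roi=list(roi),
                   caller_id=caller_id)


# ---------------------------------------------------------------------------
# VCF round-trip (explicit reference calls use 0/0)
# ---------------------------------------------------------------------------

_GT_CODE = {"ref/ref": (0, 0), "ref/alt": (0, 1), "alt/alt": (1, 1),
            "no-call": (None, None)}
_CODE_GT = {v: k for k, v in _GT_CODE.items()}


def write_calls_vcf(
    calls: list[VariantCall],
    path: str | Path,
    contig: str,
    contig_length: int,
    sample_id: str = "sample",
    *,
    panel_version: str | None = None,
) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    if panel_version is not None:
        header.add_line(f"##tmf_version={panel_version}")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    header.add_line('##FORMAT=<ID=AO,Number=1,Type=Integer,Description='
                    '"Alt observations">')
    header.add_line('##FORMAT=<ID=UAO,Number=1,Type=Integer,Description='
                    '"Unique-start alt observations">')
    header.add_line('##FILTER=<ID=fail,Description="Failed variant-level QC">')
    header.add_samples([sample_id])
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in sorted(calls, key=lambda x: x.site.pos):
            rec = vf.new_record(contig=contig, start=c.site.pos,
                                alleles=(c.site.ref, c.site.alt))
            rec.samples[sample_id]["GT"] = _GT_CODE[c.genotype]
            rec.samples[sample_id]["DP"] = c.DP
            rec.samples[sample_id]["AO"] = c.AO
            rec.samples[sample_id]["UAO"] = c.UAO
            rec.filter.add("fail" if c.filters else "PASS")
            vf.write(rec)


def load_calls_vcf(path: str | Path) -> list[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            fmt = rec.samples[sample]
            gt = _CODE_GT.get(tuple(fmt.get("GT") or (None, None)), "no-call")
            dp = fmt.get("DP") or 0
            ao = fmt.get("AO") or 0
            uao = fmt.get("UAO") or 0
            out.append(VariantCall(
                site=Variant(rec.start, rec.ref, rec.alts[0]),
                genotype=gt, DP=dp, AO=ao, UAO=uao,
                AF=(ao / dp if dp else 0.0),
                filters=[] if "PASS" in rec.filter or not list(rec.filter)
                else list(rec.filter),
            ))
    return out


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConcordanceResult:
    TP: int
    FP: int
    FN: int
    TN: int | None = None
    discordant: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        assert min(self.TP, self.FP, self.FN) >= 0

    @property
    def sensitivity(self) -> float | None:
        if self.TP + self.FN == 0:
            return None
        return 100.0 * self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float | None:
        if self.TN is None:
            return None
        if self.TN + self.FP == 0:
            return None
        return 100.0 * self.TN / (self.TN + self.FP)

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ConcordanceResult":
        """Confusion-table arithmetic on externally tabulated counts."""
        return cls(TP=tp, FP=fp, FN=fn, TN=tn)


def concordance_pct(concordant: int, total: int) -> float:
    """Printed-style concordance percentage (one decimal)."""
    return round(100.0 * concordant / total, 1)


def compare_callsets(
    eval_cs: Callset,
    truth_cs: Callset,
    *,
    n_negative_sites: int | None = None,
) -> ConcordanceResult:
    """Match normalized (variant, genotype) pairs between an evaluated and a
    truth callset over the same ROI. A genotype disagreement at a shared site
    counts as both FP and FN and is listed as discordant. Specificity needs a
    universe of negative sites; by default the ROI base count stands in."""
    if eval_cs.roi != truth_cs.roi:
        raise ValueError("callsets cover different regions of interest")
    ev = {c.site: c.genotype for c in eval_cs.calls if c.is_alt}
    tr = {c.site: c.genotype for c in truth_cs.calls if c.is_alt}
    tp = fp = fn = 0
    discordant = []
    for site, gt in tr.items():
        if site in ev:
            if ev[site] == gt:
                tp += 1
            else:
                fp += 1
                fn += 1
                discordant.append((site, ev[site], gt))
        else:
            fn += 1
            discordant.append((site, None, gt))
    for site, gt in ev.items():
        if site not in tr:
            fp += 1
            discordant.append((site, gt, None))
    if n_negative_sites is None:
        n_negative_sites = sum(e - s for s, e in truth_cs.roi) - len(tr)
    tn = max(n_negative_sites - fp, 0)
    return ConcordanceResult(TP=tp, FP=fp, FN=fn, TN=tn, discordant=discordant)


# ---------------------------------------------------------------------------
# tier merging
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MergedCall:
    site: Variant
    genotype: str
    provenance: str                 # 'tier2', 'tier3', 'both'
    needs_confirmation: bool
    entry: object = None            # TmfEntry for panel sites
    candidates: list = dataclasses.field(default_factory=list)

    @property
    def discordant_genotypes(self) -> bool:
        return len({g for g, _src in self.candidates}) > 1


def merge_tiers(
    tier2_calls: list[VariantCall],
    tier3: Callset,
) -> list[MergedCall]:
    """Union of alternate calls from both tiers with per-variant provenance.

    Agreement yields one merged genotype; disagreement keeps both candidate
    genotypes on the record. Every reportable variant is flagged
    needs_confirmation pending orthogonal confirmation — that is screening
    policy, not a statement of doubt.
    """
    by_site: dict[Variant, MergedCall] = {}
    for c in tier2_calls:
        if not c.is_alt:
            continue
        by_site[c.site] = MergedCall(
            site=c.site, genotype=c.genotype, provenance="tier2",
            needs_confirmation=True, entry=c.entry,
            candidates=[(c.genotype, "tier2")],
        )
    for c in tier3.calls:
        if not c.is_alt:
            continue
        m = by_site.get(c.site)
        if m is None:
            by_site[c.site] = MergedCall(
                site=c.site, genotype=c.genotype, provenance="tier3",
                needs_confirmation=True,
                candidates=[(c.genotype, "tier3")],
            )
        else:
            m.provenance = "both"
            m.candidates.append((c.genotype, "tier3"))
    return [by_site[k] for k in sorted(by_site)]
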