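"""End-to-end orchestration: reads -> dedup/QC -> tier 2 -> tier 3 -> merge.

Also provides the simulated validation cohorts used to characterize the
pipeline: a mixed SNV/indel cohort with planted panel and off-panel variants
(parameter recovery against truth) and a reproducibility design running the
same genotype profiles as independent replicates with fresh seeds and
barcode pools.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dedup import (DedupResult, QcPolicy, QcResult, SampleQcMetrics,
                    compute_sample_metrics, deduplicate, gsp2_fragment_counts,
                    sample_qc)
from .deldup import CnvPolicy, cnv_call, combine, sv_call
from .genotyper import genotype_panel
from .panel import TmfEntry, entry_by_legacy
from .pileup import FragmentPileup
from .polytgt import call_diplotype, count_spanning, enumerate_haplotypes
from .simulate import (PlantedVariant, SampleTruth, SimulatedSample,
                       draw_polytgt_diplotype, simulate_sample)
from .snv import Callset, ConcordanceResult, call_region, compare_callsets, merge_tiers
from .variants import Variant, VariantCall, VariantFilters


@dataclasses.dataclass
class SampleResult:
    sample_id: str
    dedup: DedupResult
    metrics: SampleQcMetrics
    qc: QcResult
    tier2: list[VariantCall]
    tier3: Callset
    merged: list
    polytgt: object

    @property
    def merged_signature(self) -> frozenset:
        """Reportable genotype content, for replicate concordance."""
        return frozenset((m.site, m.genotype) for m in self.merged)


def run_sample(
    ref,
    sample: SimulatedSample,
    panel: list[TmfEntry],
    *,
    filters: VariantFilters = VariantFilters(),
    qc_policy: QcPolicy = QcPolicy(),
) -> SampleResult:
    dd = deduplicate(sample.reads, ref.sequence, gsp2_sites=ref.gsp2_sites)
    roi = ref.roi()
    metrics = compute_sample_metrics(dd.fragments, roi)
    qc = sample_qc(metrics, qc_policy)
    pileup = FragmentPileup(dd.fragments, ref.sequence)
    tier2 = genotype_panel(panel, pileup, filters)
    tier3 = call_region(
        dd.fragments, roi, ref.sequence, filters=filters,
        mask=[ref.polytgt_mask()], sample_id=sample.sample_id, pileup=pileup,
    )
    merged = merge_tiers(tier2, tier3)
    haps = enumerate_haplotypes()
    counts, total = count_spanning(
        [f.consensus for f in dd.fragments], haps,
        source="bam", locus=ref.polytgt_locus,
    )
    poly = call_diplotype(counts, total)
    return SampleResult(sample.sample_id, dd, metrics, qc, tier2, tier3,
                        merged, poly)


def run_deldup(ref, fragments, normals, *, policy: CnvPolicy = CnvPolicy(),
               exclude_gsp2: tuple[str, ...] = ()):
    """Both del/dup paths plus their combination for one sample."""
    sv = sv_call(fragments, ref.breakpoints, ref)
    counts = gsp2_fragment_counts(fragments, ref.gsp2_ids)
    cnv = cnv_call(counts, normals, ref, policy, exclude_gsp2=exclude_gsp2)
    return combine(sv, cnv), sv, cnv


# ---------------------------------------------------------------------------
# validation cohort: SNV/indel parameter recovery
# ---------------------------------------------------------------------------

def _truth_callset(ref, truth: SampleTruth, roi) -> Callset:
    calls = []
    for pv in truth.planted_snv_indels:
        from .variants import normalize_variant
        v = normalize_variant(pv.pos, pv.ref, pv.alt, ref.sequence)
        gt = "alt/alt" if pv.zygosity == "hom" else "ref/alt"
        calls.append(VariantCall(site=v, genotype=gt, DP=1, AO=1, UAO=1, AF=1.0))
    return Callset(sample_id=truth.sample_id, calls=calls, roi=list(roi),
                   caller_id="truth")


def _random_exonic_snv(ref, rng, taken: list[tuple[int, int]],
                       min_gap: int = 25) -> PlantedVariant:
    while True:
        ex = ref.exons[int(rng.integers(0, len(ref.exons)))]
        pos = int(rng.integers(ex.start + 12, ex.end - 12))
        if any(a - min_gap < pos < b + min_gap for a, b in taken):
            continue
        base = ref.sequence[pos]
        alt = [b for b in "ACGT" if b != base][int(rng.integers(0, 3))]
        return PlantedVariant(pos, base, alt, "het")


def validation_cohort_truths(
    ref,
    panel: list[TmfEntry],
    n_samples: int,
    seed: int,
    *,
    target_unique_fragments: int = 24000,
    error_rate: float = 0.002,
) -> list[SampleTruth]:
    """Per-sample truths with 0-2 panel variants and 0-1 off-panel exonic
    SNV each (pairwise separated so planted alleles do not collide), plus a
    population-frequency polyTG/T diplotype."""
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_samples):
        planted: list[PlantedVariant] = []
        taken: list[tuple[int, int]] = []
        n_panel = int(rng.integers(0, 3))
        tries = 0
        while len(planted) < n_panel and tries < 100:
            tries += 1
            e = panel[int(rng.integers(0, len(panel)))]
            v = e.variant
            if any(a - 25 < v.pos < b + 25 for a, b in taken):
                continue
            zyg = "hom" if rng.random() < 0.15 else "het"
            planted.append(PlantedVariant(e.pos - 1, e.ref, e.alt, zyg))
            taken.append((v.pos, v.end))
        if rng.random() < 0.5:
            planted.append(_random_exonic_snv(ref, rng, taken))
        truths.append(SampleTruth(
            sample_id=f"V{i + 1:03d}",
            planted_snv_indels=planted,
            polytgt_diplotype=draw_polytgt_diplotype(rng),
            target_unique_fragments=target_unique_fragments,
            error_rate=error_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return truths


def cohort_merged_concordance(
    ref,
    panel: list[TmfEntry],
    truths: list[SampleTruth],
    *,
    filters: VariantFilters = VariantFilters(),
) -> ConcordanceResult:
    """Run the full SNV/indel pipeline per sample and pool the confusion
    counts of merged (tier 2 + tier 3) genotypes against truth."""
    roi = ref.roi()
    tp = fp = fn = tn = 0
    discordant = []
    for truth in truths:
        sample = simulate_sample(ref, truth)
        res = run_sample(ref, sample, panel, filters=filters)
        eval_calls = [
            VariantCall(site=m.site, genotype=m.genotype, DP=1, AO=1, UAO=1,
                        AF=1.0)
            for m in res.merged
        ]
        eval_cs = Callset(truth.sample_id, eval_calls, list(roi), "merged")
        r = compare_callsets(eval_cs, _truth_callset(ref, truth, roi))
        tp += r.TP
        fp += r.FP
        fn += r.FN
        tn += r.TN
        discordant.extend((truth.sample_id, d) for d in r.discordant)
    return ConcordanceResult(TP=tp, FP=fp, FN=fn, TN=tn, discordant=discordant)


# ---------------------------------------------------------------------------
# reproducibility design
# ---------------------------------------------------------------------------

def replicate_profiles(ref, panel: list[TmfEntry]) -> dict[str, dict]:
    """Six genotype profiles spanning the reportable variant classes."""
    f508 = entry_by_legacy(panel, "F508del")
    i507 = entry_by_legacy(panel, "I507del")
    r117h = entry_by_legacy(panel, "R117H")
    l218x = entry_by_legacy(panel, "L218X")
    some = [e for e in panel if not e.legacy_name][10]
    ex15 = ref.exons[14]
    off_pos = (ex15.start + ex15.end) // 2
    off_alt = [b for b in "ACGT" if b != ref.sequence[off_pos]][0]

    def pv(e: TmfEntry, zyg: str) -> PlantedVariant:
        return PlantedVariant(e.pos - 1, e.ref, e.alt, zyg)

    return {
        "F508del_het": {"snv": [pv(f508, "het")], "poly": ((11, 7), (11, 7))},
        "compound_het_I507del_F508del": {
            "snv": [pv(i507, "het"), pv(f508, "het")],
            "poly": ((11, 7), (11, 7)),
        },
        "R117H_5T12TG_carrier": {
            "snv": [pv(r117h, "het")], "poly": ((12, 5), (11, 7)),
        },
        "L218X_hom": {"snv": [pv(l218x, "hom")], "poly": ((11, 7), (11, 7))},
        "panel_plus_offpanel": {
            "snv": [pv(some, "het"),
                    PlantedVariant(off_pos, ref.sequence[off_pos], off_alt,
                                   "het")],
            "poly": ((10, 7), (11, 7)),
        },
        "no_variants": {"snv": [], "poly": ((11, 7), (11, 7))},
    }


def replicate_concordance(
    ref,
    panel: list[TmfEntry],
    *,
    n_replicates: int = 3,
    seed: int = 0,
    target_unique_fragments: int = 24000,
    error_rate: float = 0.002,
) -> tuple[float, dict[str, list]]:
    """Run each profile ``n_replicates`` times with fresh seeds (hence fresh
    barcode pools) and score pairwise concordance of the full reportable
    content — merged genotypes plus the polyTG/T diplotype — within each
    profile. Returns (percent concordant pairs, per-profile signatures)."""
    rng = np.random.default_rng(seed)
    profiles = replicate_profiles(ref, panel)
    signatures: dict[str, list] = {}
    concordant = total = 0
    for name, prof in profiles.items():
        sigs = []
        for rep in range(n_replicates):
            truth = SampleTruth(
                sample_id=f"{name}.r{rep}",
                planted_snv_indels=list(prof["snv"]),
                polytgt_diplotype=prof["poly"],
                target_unique_fragments=target_unique_fragments,
                error_rate=error_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            res = run_sample(ref, simulate_sample(ref, truth), panel)
            sigs.append((res.merged_signature, res.polytgt.legacy_diplotype,
                         res.polytgt.status))
        signatures[name] = sigs
        for a in range(len(sigs)):
            for b in range(a + 1, len(sigs)):
                total += 1
                concordant += int(sigs[a] == sigs[b])
    return 100.0 * concordant / total, signatures
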