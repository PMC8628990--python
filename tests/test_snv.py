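import random

import pytest

import tierseq as tq
from tierseq.dedup import deduplicate
from tierseq.panel import entry_by_legacy
from tierseq.simulate import PlantedVariant, SampleTruth, simulate_sample
from tierseq.snv import (Callset, ConcordanceResult, call_region,
                         compare_callsets, load_calls_vcf, merge_tiers,
                         write_calls_vcf)
from tierseq.variants import Variant, VariantCall, normalize_variant


def vc(pos, ref_a, alt_a, gt="ref/alt"):
    return VariantCall(site=Variant(pos, ref_a, alt_a), genotype=gt,
                       DP=100, AO=50, UAO=20, AF=0.5)


def mk_cs(calls, roi=((0, 1000),), sample="s", caller="c"):
    return Callset(sample, list(calls), [tuple(i) for i in roi], caller)


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def test_planted_variants_discovered_exactly(ref, het_truth, het_result):
    truth_sites = {
        normalize_variant(pv.pos, pv.ref, pv.alt, ref.sequence)
        for pv in het_truth.planted_snv_indels
    }
    called = {c.site for c in het_result.tier3.calls}
    assert called == truth_sites
    for c in het_result.tier3.calls:
        assert c.genotype == "ref/alt"
        assert 0.35 <= c.AF <= 0.65


def test_compound_het_adjacent_deletions_both_called(ref, panel):
    """Adjacent overlapping 3-bp deletions on opposite haplotypes must both
    come out heterozygous; neither allele's reads may suppress the other."""
    f508 = entry_by_legacy(panel, "F508del")
    i507 = entry_by_legacy(panel, "I507del")
    truth = SampleTruth(
        sample_id="CH",
        planted_snv_indels=[
            PlantedVariant(i507.pos - 1, i507.ref, i507.alt, "het"),
            PlantedVariant(f508.pos - 1, f508.ref, f508.alt, "het"),
        ],
        target_unique_fragments=6000, seed=21)
    frags = deduplicate(simulate_sample(ref, truth).reads, ref.sequence).fragments
    cs = call_region(frags, ref.roi(), ref.sequence,
                     mask=[ref.polytgt_mask()])
    by_site = {c.site: c for c in cs.calls}
    assert i507.variant in by_site and f508.variant in by_site
    assert by_site[i507.variant].genotype == "ref/alt"
    assert by_site[f508.variant].genotype == "ref/alt"


def test_clean_sample_yields_empty_callset(ref):
    truth = SampleTruth(sample_id="CLEAN", target_unique_fragments=4000,
                        seed=33)
    frags = deduplicate(simulate_sample(ref, truth).reads, ref.sequence).fragments
    cs = call_region(frags, ref.roi(), ref.sequence, mask=[ref.polytgt_mask()])
    assert cs.calls == []


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_identical_callsets_fully_concordant():
    calls = [vc(10, "A", "T"), vc(50, "C", "G", "alt/alt")]
    r = compare_callsets(mk_cs(calls), mk_cs(calls))
    assert (r.TP, r.FP, r.FN) == (2, 0, 0)
    assert r.sensitivity == 100.0
    assert r.specificity == 100.0


def test_partial_recall_arithmetic():
    truth = [vc(10, "A", "T"), vc(20, "A", "T"), vc(30, "A", "T")]
    ev = truth[:2]
    r = compare_callsets(mk_cs(ev), mk_cs(truth))
    assert (r.TP, r.FN, r.FP) == (2, 1, 0)
    assert round(r.sensitivity, 1) == 66.7


def test_genotype_mismatch_counts_both_ways():
    truth = [vc(10, "A", "T", "ref/alt")]
    ev = [vc(10, "A", "T", "alt/alt")]
    r = compare_callsets(mk_cs(ev), mk_cs(truth))
    assert (r.TP, r.FP, r.FN) == (0, 1, 1)
    assert r.discordant


def test_random_callsets_match_set_arithmetic_oracle():
    rnd = random.Random(5)
    truth = [vc(p, "A", "T") for p in rnd.sample(range(1, 900), 20)]
    ev = [c for c in truth if rnd.random() < 0.7] + \
        [vc(p, "C", "G") for p in rnd.sample(range(900, 990), 4)]
    r = compare_callsets(mk_cs(ev), mk_cs(truth))
    tset = {c.site for c in truth}
    eset = {c.site for c in ev}
    assert r.TP == len(tset & eset)
    assert r.FN == len(tset - eset)
    assert r.FP == len(eset - tset)


def test_swap_symmetry_exchanges_fp_and_fn():
    rnd = random.Random(11)
    truth = [vc(p, "A", "T") for p in rnd.sample(range(1, 500), 10)]
    ev = truth[:6] + [vc(p, "C", "G") for p in rnd.sample(range(500, 900), 3)]
    fwd = compare_callsets(mk_cs(ev), mk_cs(truth))
    rev = compare_callsets(mk_cs(truth), mk_cs(ev))
    assert fwd.TP == rev.TP
    assert (fwd.FP, fwd.FN) == (rev.FN, rev.FP)


def test_roi_mismatch_rejected():
    with pytest.raises(ValueError):
        compare_callsets(mk_cs([], roi=((0, 10),)), mk_cs([], roi=((0, 20),)))


def test_confusion_arithmetic_from_counts():
    r = ConcordanceResult.from_counts(tp=2, fp=0, tn=8, fn=1)
    assert round(r.sensitivity, 1) == 66.7
    assert r.specificity == 100.0


# ---------------------------------------------------------------------------
# tier merging
# ---------------------------------------------------------------------------

def test_merge_agreeing_tiers_single_record():
    t2 = [vc(10, "A", "T")]
    t3 = mk_cs([vc(10, "A", "T")])
    merged = merge_tiers(t2, t3)
    assert len(merged) == 1
    m = merged[0]
    assert m.provenance == "both"
    assert m.needs_confirmation
    assert not m.discordant_genotypes


def test_tier2_only_variant_kept_and_flagged():
    merged = merge_tiers([vc(10, "A", "T")], mk_cs([]))
    assert len(merged) == 1
    assert merged[0].provenance == "tier2"
    assert merged[0].needs_confirmation


def test_disjoint_tiers_yield_two_flagged_records():
    merged = merge_tiers([vc(10, "A", "T")], mk_cs([vc(50, "C", "G")]))
    assert len(merged) == 2
    assert all(m.needs_confirmation for m in merged)
    assert {m.provenance for m in merged} == {"tier2", "tier3"}


def test_genotype_disagreement_keeps_both_candidates():
    merged = merge_tiers([vc(10, "A", "T", "ref/alt")],
                         mk_cs([vc(10, "A", "T", "alt/alt")]))
    assert len(merged) == 1
    assert merged[0].discordant_genotypes
    assert merged[0].needs_confirmation


def test_every_tier2_alt_call_survives_merge(het_result):
    t2_alt = {c.site for c in het_result.tier2 if c.is_alt}
    merged_sites = {m.site for m in het_result.merged}
    assert t2_alt <= merged_sites


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

def test_calls_vcf_round_trip(tmp_path, ref):
    calls = [
        VariantCall(site=Variant(100, "A", "T"), genotype="ref/alt",
                    DP=80, AO=40, UAO=12, AF=0.5),
        VariantCall(site=Variant(200, "CAT", "C"), genotype="alt/alt",
                    DP=60, AO=58, UAO=15, AF=58 / 60),
        VariantCall(site=Variant(300, "G", "GA"), genotype="ref/ref",
                    DP=90, AO=0, UAO=0, AF=0.0),
    ]
    path = tmp_path / "calls.vcf"
    write_calls_vcf(calls, path, ref.contig_name, len(ref.sequence), "S1")
    loaded = load_calls_vcf(path)
    assert [(c.site, c.genotype, c.DP, c.AO) for c in loaded] == \
        [(c.site, c.genotype, c.DP, c.AO) for c in calls]
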