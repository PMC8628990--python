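import random
import warnings

import numpy as np
import pandas as pd
import pytest

from tierseq.dedup import deduplicate, gsp2_fragment_counts
from tierseq.deldup import (BreakpointRecord, CnvPolicy, DelDupCall,
                            cnv_call, cnv_ratios, combine, junction_kmer,
                            load_breakpoints, sv_call)
from tierseq.pipeline import run_deldup
from tierseq.simulate import PlantedDelDup, SampleTruth, simulate_sample


def frags_for(ref, truth):
    return deduplicate(simulate_sample(ref, truth).reads, ref.sequence).fragments


def flat_counts(ref, base=340.0):
    return pd.Series(base, index=ref.gsp2_ids)


def test_junction_kmer_geometry(ref):
    bp = ref.breakpoints[0]
    k = junction_kmer(ref.sequence, bp, flank=12)
    assert k == ref.sequence[bp.left - 12:bp.left] + \
        ref.sequence[bp.right:bp.right + 12]
    dup = next(b for b in ref.breakpoints if b.type == "dup")
    k = junction_kmer(ref.sequence, dup, flank=12)
    assert k == ref.sequence[dup.right - 12:dup.right] + \
        ref.sequence[dup.left:dup.left + 12]


def test_known_breakpoint_deletion_called_by_sv(ref, normals):
    bp = ref.breakpoints[0]   # CFTRdele2,3 analog
    truth = SampleTruth(sample_id="SV1",
                        planted_deldups=[PlantedDelDup(bp.left, bp.right, -1,
                                                       True, bp.name)],
                        seed=51)
    frags = frags_for(ref, truth)
    combined, sv, cnv = run_deldup(ref, frags, normals)
    assert [c.name for c in sv] == [bp.name]
    assert sv[0].junction_reads >= 3
    assert sv[0].type == "del"
    # CNV sees it too and the merged record carries both evidence paths
    assert any(c.type == "del" for c in cnv)
    assert len(combined) == 1 and combined[0].evidence == "both"
    assert not combined[0].validated


def test_small_intraexonic_deletion_sv_only(ref, normals):
    """An 84-bp in-exon deletion is junction-detectable but leaves GSP2
    molecular counts untouched, so the CNV path is blind to it."""
    bp = next(b for b in ref.breakpoints if b.name == "1949del84")
    truth = SampleTruth(sample_id="SV84",
                        planted_deldups=[PlantedDelDup(bp.left, bp.right, -1,
                                                       True)],
                        seed=52)
    frags = frags_for(ref, truth)
    _combined, sv, cnv = run_deldup(ref, frags, normals)
    assert [c.name for c in sv] == ["1949del84"]
    assert cnv == []


def test_untargeted_deletion_cnv_only(ref, normals):
    """A multi-exon deletion without a database breakpoint is invisible to
    the SV path but flagged by coverage over >=4 GSP2s."""
    s, e = ref.exons[4].start - 50, ref.exons[7].end + 50
    truth = SampleTruth(sample_id="CNV1",
                        planted_deldups=[PlantedDelDup(s, e, -1, False)],
                        seed=53)
    frags = frags_for(ref, truth)
    _combined, sv, cnv = run_deldup(ref, frags, normals)
    assert sv == []
    assert len(cnv) == 1
    call = cnv[0]
    assert call.type == "del"
    assert (call.exon_first, call.exon_last) == (5, 8)
    assert abs(call.copy_ratio - 0.5) < 0.1
    assert not call.low_confidence


def test_duplication_detected_by_both_paths(ref, normals):
    bp = next(b for b in ref.breakpoints if b.type == "dup")
    truth = SampleTruth(sample_id="DUP1",
                        planted_deldups=[PlantedDelDup(bp.left, bp.right, +1,
                                                       True)],
                        seed=54)
    frags = frags_for(ref, truth)
    combined, sv, cnv = run_deldup(ref, frags, normals)
    assert [c.name for c in sv] == [bp.name]
    assert any(c.type == "dup" and c.copy_ratio > 1.3 for c in cnv)
    assert combined[0].evidence == "both"


def test_no_junction_reads_no_sv_calls(ref, normals):
    truth = SampleTruth(sample_id="CLEAN", target_unique_fragments=4000,
                        seed=55)
    frags = frags_for(ref, truth)
    assert sv_call(frags, ref.breakpoints, ref) == []


def test_sv_specificity_on_clean_cohort(ref):
    """Zero SV calls across 50 event-free samples at error rate 0.005."""
    total_calls = 0
    for seed in range(50):
        truth = SampleTruth(sample_id=f"NEG{seed}", error_rate=0.005,
                            target_unique_fragments=2500, seed=600 + seed)
        frags = frags_for(ref, truth)
        total_calls += len(sv_call(frags, ref.breakpoints, ref))
    assert total_calls == 0


# ---------------------------------------------------------------------------
# CNV statistics
# ---------------------------------------------------------------------------

def test_unit_ratios_produce_no_calls(ref, normals):
    calls = cnv_call(flat_counts(ref), normals, ref)
    assert calls == []


def test_ratio_estimator_noise_free(ref):
    """On a noise-free panel the per-GSP2 ratio recovers the planted copy
    ratio to within 0.05."""
    from tierseq.simulate import simulate_normals
    clean = simulate_normals(ref, 10, seed=1, sample_sigma=0.0,
                             count_noise=False)
    sample = flat_counts(ref, base=float(clean.iloc[0, 0]))
    targets = [g.gsp2_id for g in ref.gsp2_sites if g.exon_number == 12]
    sample[targets] = sample[targets] * 0.5
    table = cnv_ratios(sample, clean)
    for g in targets:
        assert abs(table.at[g, "ratio"] - 0.5) < 0.05
    others = [g for g in ref.gsp2_ids if g not in targets]
    assert np.allclose(table.loc[others, "ratio"], 1.0, atol=0.05)


def test_excluded_gsp2_never_contributes(ref, normals):
    sample = flat_counts(ref)
    targets = [g.gsp2_id for g in ref.gsp2_sites if g.exon_number == 20]
    sample[targets] = sample[targets] * 0.4
    with_calls = cnv_call(sample, normals, ref)
    assert any(c.type == "del" for c in with_calls)
    silenced = cnv_call(sample, normals, ref, exclude_gsp2=tuple(targets))
    assert silenced == []


def test_single_gsp2_event_low_confidence(ref, normals):
    sample = flat_counts(ref)
    g = next(x.gsp2_id for x in ref.gsp2_sites if x.exon_number == 3)
    sample[g] = sample[g] * 0.4
    calls = cnv_call(sample, normals, ref)
    assert len(calls) == 1 and calls[0].low_confidence


def test_zero_median_gsp2_masked(ref, normals):
    broken = normals.copy()
    broken.iloc[0, :] = 0
    with pytest.warns(UserWarning, match="masked"):
        table = cnv_ratios(flat_counts(ref), broken)
    assert np.isnan(table.iloc[0]["p_value"])


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def call_at(lo, hi, kind, ev):
    return DelDupCall(interval=(lo, hi), type=kind, exon_first=1, exon_last=2,
                      exon_label="exons 1-2", evidence=ev)


def test_disjoint_paths_union():
    out = combine([call_at(0, 100, "del", "SV")],
                  [call_at(500, 900, "dup", "CNV")])
    assert len(out) == 2
    assert all(not c.validated for c in out)


def test_same_event_merges_to_both():
    out = combine([call_at(0, 100, "del", "SV")],
                  [call_at(20, 150, "del", "CNV")])
    assert len(out) == 1
    assert out[0].evidence == "both"
    assert out[0].interval == (0, 100)   # breakpoint-precise SV interval wins


def test_combined_sensitivity_dominates_each_path():
    """Union property: on any truth set, combined recall >= each alone."""
    rnd = random.Random(9)
    for _ in range(30):
        truth = [(i * 1000, i * 1000 + rnd.randrange(100, 800),
                  rnd.choice(["del", "dup"])) for i in range(8)]
        sv = [call_at(a, b, t, "SV") for a, b, t in truth if rnd.random() < 0.6]
        cnv = [call_at(a, b, t, "CNV") for a, b, t in truth if rnd.random() < 0.5]
        comb = combine(sv, cnv)

        def recall(calls):
            hit = 0
            for a, b, t in truth:
                probe = call_at(a, b, t, "x")
                hit += any(c.overlaps(probe) for c in calls)
            return hit
        assert recall(comb) >= max(recall(sv), recall(cnv))


def test_breakpoint_db_round_trip(tmp_path, ref):
    path = tmp_path / "bp.tsv"
    ref.write_breakpoints_tsv(path)
    loaded = load_breakpoints(path)
    assert loaded == ref.breakpoints
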