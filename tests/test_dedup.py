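import random

import numpy as np
import pytest

from tierseq.dedup import (QcPolicy, SampleQcMetrics, coverage_report,
                           deduplicate, sample_qc, summarize_depth)
from tierseq.reads import AlignedRead


def mk_read(name="r", start=100, strand="+", seq=None, barcode="AAACCCGGGTTT",
            gsp2="E01F", site=None, ref=None):
    if seq is None:
        seq = ref[start:start + 30]
    return AlignedRead(name=name, start=start, strand=strand,
                       cigar=[("M", len(seq))], seq=seq, barcode=barcode,
                       gsp2_id=gsp2, start_site=site)


def test_shared_key_collapses_to_one_fragment(ref):
    reads = [mk_read(name=f"r{i}", ref=ref.sequence, site=130) for i in range(3)]
    res = deduplicate(reads, ref.sequence)
    assert len(res.fragments) == 1
    assert res.fragments[0].read_count == 3


def test_distinct_barcodes_stay_separate(ref):
    reads = [mk_read(name="a", barcode="A" * 12, ref=ref.sequence, site=130),
             mk_read(name="b", barcode="C" * 12, ref=ref.sequence, site=130)]
    res = deduplicate(reads, ref.sequence)
    assert len(res.fragments) == 2


def test_missing_barcode_dropped_with_warning(ref):
    reads = [mk_read(ref=ref.sequence, site=130),
             mk_read(name="nobc", barcode=None, ref=ref.sequence, site=130)]
    with pytest.warns(UserWarning, match="without barcode"):
        res = deduplicate(reads, ref.sequence)
    assert res.dropped_missing_barcode == 1
    assert len(res.fragments) == 1


def test_fragment_count_matches_brute_force_oracle(ref):
    """On a random 500-read instance, the fragment count equals the
    brute-force count of distinct (barcode, start site, strand, GSP2) keys
    and read counts sum to the input size."""
    rnd = random.Random(17)
    reads = []
    for i in range(500):
        bc = "".join(rnd.choice("ACGT") for _ in range(3)) * 4  # small pool
        strand = rnd.choice("+-")
        start = rnd.randrange(300, 400)
        site = start + 30 if strand == "+" else start
        gsp2 = rnd.choice(["E01F", "E01R", "E02F"])
        reads.append(mk_read(name=f"r{i}", start=start, strand=strand,
                             barcode=bc, gsp2=gsp2, site=site,
                             ref=ref.sequence))
    expected = len({(r.barcode, r.start_site, r.strand, r.gsp2_id)
                    for r in reads})
    res = deduplicate(reads, ref.sequence)
    assert len(res.fragments) == expected
    assert sum(f.read_count for f in res.fragments) == 500


def test_consensus_majority_and_reference_tiebreak(ref):
    start = 100
    base = ref.sequence[start:start + 30]
    alt = "A" if base[5] != "A" else "G"
    mutated = base[:5] + alt + base[6:]
    # 2-1 majority for the non-reference base
    reads = [mk_read(name=f"m{i}", seq=mutated, ref=ref.sequence, site=130)
             for i in range(2)] + [mk_read(name="w", seq=base,
                                           ref=ref.sequence, site=130)]
    res = deduplicate(reads, ref.sequence)
    assert res.fragments[0].consensus.seq[5] == alt
    # 1-1 tie resolves to the reference base
    reads = [mk_read(name="x", seq=mutated, ref=ref.sequence, site=130),
             mk_read(name="y", seq=base, ref=ref.sequence, site=130)]
    res = deduplicate(reads, ref.sequence)
    assert res.fragments[0].consensus.seq[5] == base[5]


def test_read_order_never_changes_fragments(ref, het_sample):
    reads = list(het_sample.reads[:2000])
    a = deduplicate(reads, ref.sequence)
    shuffled = list(reads)
    random.Random(3).shuffle(shuffled)
    b = deduplicate(shuffled, ref.sequence)
    key = lambda f: (f.barcode, f.start_site, f.gsp2_id)
    assert sorted((key(f), f.read_count, f.consensus.seq) for f in a) == \
        sorted((key(f), f.read_count, f.consensus.seq) for f in b)


def test_dedup_idempotent_on_consensus_reads(ref, het_sample):
    once = deduplicate(het_sample.reads[:5000], ref.sequence)
    twice = deduplicate([f.consensus for f in once.fragments], ref.sequence)
    assert len(twice.fragments) == len(once.fragments)
    assert all(f.read_count == 1 for f in twice.fragments)


# ---------------------------------------------------------------------------
# sample-level QC gate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("frags,sites,ok,expect", [
    (20000, 30.0, True, ""),
    (19999, 30.0, False, "unique fragment total"),
    (25000, 12.0, False, "start sites"),
])
def test_sample_qc_thresholds_inclusive(frags, sites, ok, expect):
    m = SampleQcMetrics(unique_fragment_total=frags,
                        avg_unique_start_sites_per_gsp2=sites,
                        deduplicated_mean_coverage=200.0)
    r = sample_qc(m, QcPolicy())
    assert r.passed is ok
    if not ok:
        assert any(expect in reason for reason in r.reasons)


def test_sample_qc_lists_every_violation():
    m = SampleQcMetrics(100, 1.0, 5.0)
    r = sample_qc(m)
    assert len(r.reasons) == 2


# ---------------------------------------------------------------------------
# coverage report
# ---------------------------------------------------------------------------

def test_uniformity_hand_computation():
    """Depth [100 x50 bases, 70 x50 bases]: mean 85, threshold 0.8*85=68,
    so every base clears it -> uniformity 100%."""
    depth = np.array([100] * 50 + [70] * 50)
    rep = summarize_depth([(0, 100)], [depth])
    assert rep.mean_depth == pytest.approx(85.0)
    assert rep.uniformity_pct == pytest.approx(100.0)
    assert rep.low_regions == []


def test_constant_depth_coverage(ref):
    reads = [mk_read(name=f"c{i}", barcode="ACGT" * 3 + "",
                     seq=ref.sequence[100:200], start=100,
                     site=200 + i, ref=ref.sequence) for i in range(100)]
    frags = deduplicate(reads, ref.sequence).fragments
    rep = coverage_report(frags, [(100, 200)])
    assert rep.mean_depth == pytest.approx(100.0)
    assert rep.uniformity_pct == pytest.approx(100.0)
    assert rep.low_regions == []


def test_low_coverage_run_reported():
    depth = np.array([50] * 20 + [9] * 5 + [50] * 20)
    rep = summarize_depth([(1000, 1045)], [depth])
    assert rep.low_regions == [(1020, 1025)]


def test_empty_roi_rejected():
    with pytest.raises(ValueError):
        coverage_report([], [])
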