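"""Intron 9 (legacy intron 8) polyTG/T diplotyping from spanning reads.

The (TG)m(T)n tract modifies splicing — 5T reduces exon 10 inclusion and
sets the severity of R117H in cis — so its diplotype is reported alongside
sequence variants. The caller enumerates every literal haplotype motif in
the configured ranges with fixed 10+ bp flank anchors, counts reads that
fully span the tract and exactly match one motif (no mismatches; grep
semantics), and calls the diplotype from the ratio r of the two most
frequent haplotypes: r >= 0.25 heterozygous, r < 0.10 homozygous for the
top haplotype, the band between is borderline and reflexes to the orthogonal
repeat assay. Reads may come from FASTQ (either orientation) or from
alignments pre-filtered to the tract interval; on error-free data the two
modes agree exactly.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

from .reads import AlignedRead, revcomp

#: v1 script haplotype space TG(4-14)/T(2-10); v1.0.0/v2.0.0 use T(1-13).
V1_RANGES = ((4, 14), (2, 10))
CURRENT_RANGES = ((4, 14), (1, 13))


@dataclasses.dataclass(frozen=True, order=True)
class RepeatHaplotype:
    t_len: int      # first in sort order: canonical report order is by T then TG
    tg_len: int
    motif_string: str = dataclasses.field(compare=False, default="")

    @property
    def legacy_name(self) -> str:
        return f"{self.t_len}T-{self.tg_len}TG"


def enumerate_haplotypes(
    tg_range: tuple[int, int] = CURRENT_RANGES[0],
    t_range: tuple[int, int] = CURRENT_RANGES[1],
    flanks: tuple[str, str] | None = None,
) -> list[RepeatHaplotype]:
    """All (TG)m(T)n haplotypes in the closed ranges, with anchored motifs."""
    if flanks is None:
        from .reference import POLYTGT_LEFT_FLANK, POLYTGT_RIGHT_FLANK
        flanks = (POLYTGT_LEFT_FLANK, POLYTGT_RIGHT_FLANK)
    left, right = flanks
    out = []
    for tg in range(tg_range[0], tg_range[1] + 1):
        for t in range(t_range[0], t_range[1] + 1):
            motif = left + "TG" * tg + "T" * t + right
            out.append(RepeatHaplotype(t_len=t, tg_len=tg, motif_string=motif))
    assert len({h.motif_string for h in out}) == len(out)
    return out


def count_spanning(
    reads,
    haplotypes: list[RepeatHaplotype],
    *,
    source: str = "fastq",
    locus: tuple[int, int] | None = None,
) -> tuple[Counter, int]:
    """Count reads matching each haplotype; returns (counts, total_spanning).

    total_spanning counts reads containing both flank anchors in order
    (i.e. fully spanning the tract); each such read matches at most one
    haplotype motif exactly. ``source='fastq'`` takes (name, seq) pairs and
    checks both orientations; ``source='bam'`` takes alignment records,
    pre-filtered to those whose aligned interval covers the flanked tract
    (requires ``locus``), then applies the identical exact-match test.
    """
    left = haplotypes[0].motif_string
    right = haplotypes[0].motif_string
    # flanks are shared by construction: recover them from any motif
    h0 = haplotypes[0]
    core = "TG" * h0.tg_len + "T" * h0.t_len
    i = h0.motif_string.index(core)
    left = h0.motif_string[:i]
    right = h0.motif_string[i + len(core):]
    by_motif = {h.motif_string: h for h in haplotypes}

    if source == "fastq":
        seqs = (seq for _name, seq in reads)
    elif source == "bam":
        if locus is None:
            raise ValueError("bam source requires the tract locus")
        lo = locus[0] - len(left)
        hi = locus[1] + len(right)
        seqs = (r.seq for r in reads
                if isinstance(r, AlignedRead) and r.start <= lo and r.ref_end >= hi)
    else:
        raise ValueError(f"unknown source {source!r}")

    counts: Counter = Counter()
    total = 0
    for seq in seqs:
        hit = _span(seq, left, right)
        if hit is None and source == "fastq":
            hit = _span(revcomp(seq), left, right)
        if hit is None:
            continue
        total += 1
        h = by_motif.get(left + hit + right)
        if h is not None:
            counts[h] += 1
    return counts, total


def _span(seq: str, left: str, right: str) -> str | None:
    i = seq.find(left)
    if i < 0:
        return None
    j = seq.find(right, i + len(left))
    if j < 0:
        return None
    return seq[i + len(left):j]


@dataclasses.dataclass
class RepeatDiplotypeResult:
    counts: dict[RepeatHaplotype, int]
    total_spanning: int
    diplotype: tuple[RepeatHaplotype, RepeatHaplotype] | None
    status: str                  # 'called', 'borderline', 'insufficient'

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) <= self.total_spanning

    @property
    def legacy_diplotype(self) -> str | None:
        if self.diplotype is None:
            return None
        a, b = self.diplotype
        return f"{a.legacy_name}/{b.legacy_name}"


def call_diplotype(
    counts: Counter,
    total_spanning: int,
    *,
    min_spanning: int = 20,
    hom_ratio: float = 0.10,
    het_ratio: float = 0.25,
) -> RepeatDiplotypeResult:
    """Diplotype from the ratio r = count2/count1 of the two most frequent
    haplotypes: r >= het_ratio heterozygous, r < hom_ratio homozygous,
    otherwise borderline (reflex to the orthogonal assay). Fewer than
    ``min_spanning`` spanning reads is insufficient. The reported pair is in
    canonical order (by T length, then TG length)."""
    if total_spanning < min_spanning:
        return RepeatDiplotypeResult(dict(counts), total_spanning, None,
                                     "insufficient")
    ranked = counts.most_common(2)
    h1, c1 = ranked[0]
    if len(ranked) == 1 or ranked[1][1] == 0:
        return RepeatDiplotypeResult(dict(counts), total_spanning,
                                     (h1, h1), "called")
    h2, c2 = ranked[1]
    r = c2 / c1
    if r >= het_ratio:
        pair = tuple(sorted((h1, h2)))
        return RepeatDiplotypeResult(dict(counts), total_spanning, pair, "called")
    if r < hom_ratio:
        return RepeatDiplotypeResult(dict(counts), total_spanning,
                                     (h1, h1), "called")
    return RepeatDiplotypeResult(dict(counts), total_spanning, None, "borderline")
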