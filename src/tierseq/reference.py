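"""Synthetic *CFTR*-like reference contig.

The screening assay interrogates all 27 *CFTR* exons, their intron/exon
boundaries, the intron 9 (legacy intron 8) polyTG/T tract, and a set of
recurrent deletion/duplication breakpoints. For fast, download-free testing
the reference here is synthetic: exon count, exon naming (sequential plus
legacy labels such as 17b), primer anchoring and the repeat tract mirror the
real locus, while introns are compressed to ``intron_scale`` bases and the
base composition is random. Coordinates are 0-based half-open throughout;
1-based coordinates appear only at VCF boundaries. A real-genome run is a
configuration swap (FASTA + BED + primer/breakpoint tables), not a code
change.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .deldup import BreakpointRecord

#: Legacy exon labels for sequential exons 1..27 (6a/6b, 14a/14b, 17a/17b splits).
LEGACY_EXON_LABELS = [
    "1", "2", "3", "4", "5", "6a", "6b", "7", "8", "9", "10", "11", "12",
    "13", "14a", "14b", "15", "16", "17a", "17b", "18", "19", "20", "21",
    "22", "23", "24",
]

N_EXONS = 27

# Fixed anchors flanking the (TG)m(T)n tract; chosen not to extend either
# repeat (left ends in C, right starts with G then A).
POLYTGT_LEFT_FLANK = "CAGACGCATCAC"
POLYTGT_RIGHT_FLANK = "GAACCTCAGATC"

DEFAULT_TG = 11
DEFAULT_T = 7

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class Exon:
    start: int
    end: int
    number: int           # sequential, 1-based
    legacy: str

    @property
    def label(self) -> str:
        if self.legacy != str(self.number):
            return f"{self.number} ({self.legacy})"
        return str(self.number)


@dataclasses.dataclass(frozen=True)
class Gsp2Site:
    gsp2_id: str
    pos: int              # primer anchor (fragment fixed end), 0-based
    strand: str           # '+' fragment extends right, '-' extends left
    exon_number: int      # nearest exon (sequential), 0 for the tract anchors


@dataclasses.dataclass
class SyntheticReference:
    contig_name: str
    sequence: str
    exons: list[Exon]
    polytgt_locus: tuple[int, int]          # tract only (no flanks)
    gsp2_sites: list[Gsp2Site]
    breakpoints: list[BreakpointRecord]
    seed: int
    _seq_array: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def __post_init__(self) -> None:
        assert len(self.exons) == N_EXONS
        for a, b in zip(self.exons, self.exons[1:]):
            assert a.end <= b.start, "exons must be ascending and disjoint"
        s, e = self.polytgt_locus
        assert self.exons[8].end <= s and e <= self.exons[9].start, (
            "polyTG/T tract must lie in the intron between exons 9 and 10"
        )
        for bp in self.breakpoints:
            assert 0 <= bp.left < bp.right <= len(self.sequence)

    # -- accessors ---------------------------------------------------------

    @property
    def seq_array(self) -> np.ndarray:
        if self._seq_array is None:
            self._seq_array = np.frombuffer(
                self.sequence.encode("ascii"), dtype=np.uint8
            )
        return self._seq_array

    @property
    def gsp2_ids(self) -> list[str]:
        return [g.gsp2_id for g in self.gsp2_sites]

    def gsp2_by_id(self, gsp2_id: str) -> Gsp2Site:
        for g in self.gsp2_sites:
            if g.gsp2_id == gsp2_id:
                return g
        raise KeyError(gsp2_id)

    def roi(self, exon_pad: int = 20, tract_pad: int = 20) -> list[tuple[int, int]]:
        """Region of interest: padded exons plus the padded polyTG/T tract."""
        iv = [(max(0, e.start - exon_pad), min(len(self.sequence), e.end + exon_pad))
              for e in self.exons]
        s, e = self.polytgt_locus
        iv.append((s - tract_pad, e + tract_pad))
        iv.sort()
        merged: list[tuple[int, int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def polytgt_mask(self, pad: int = 12) -> tuple[int, int]:
        """Tract plus flank anchors; SNV/indel calling is masked here and the
        dedicated repeat caller owns the region."""
        s, e = self.polytgt_locus
        return (s - pad, e + pad)

    def exon_for_position(self, pos: int) -> Exon:
        """Nearest exon by midpoint distance (primers sit in flanking introns)."""
        return min(self.exons, key=lambda ex: abs((ex.start + ex.end) // 2 - pos))

    # -- serialization -----------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig_name}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i:i + width] + "\n")

    def write_exon_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ex in self.exons:
                fh.write(f"{self.contig_name}\t{ex.start}\t{ex.end}\t"
                         f"exon{ex.number}|{ex.legacy}\n")

    def write_roi_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, e in self.roi():
                fh.write(f"{self.contig_name}\t{s}\t{e}\n")

    def write_gsp2_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gsp2_id\tpos\tstrand\texon\n")
            for g in self.gsp2_sites:
                fh.write(f"{g.gsp2_id}\t{g.pos}\t{g.strand}\t{g.exon_number}\n")

    def write_breakpoints_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tleft\tright\ttype\tsource\n")
            for bp in self.breakpoints:
                fh.write(f"{bp.name}\t{bp.left}\t{bp.right}\t{bp.type}\t{bp.source}\n")


class ReferenceSizingError(ValueError):
    """intron_scale too small to fit primer anchors and the repeat tract."""


def _ensure_unique(seq: np.ndarray, motif: str, keep_at: int) -> None:
    """Force `motif` to occur only at `keep_at` by mutating one base of any
    other occurrence (deterministic: cycle A->C->G->T->A)."""
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    k = len(m)
    while True:
        windows = np.lib.stride_tricks.sliding_window_view(seq, k)
        hits = np.nonzero((windows == m).all(axis=1))[0]
        hits = hits[hits != keep_at]
        if hits.size == 0:
            return
        i = int(hits[0]) + k // 2
        cycle = {65: 67, 67: 71, 71: 84, 84: 65}
        seq[i] = cycle[int(seq[i])]


def make_reference(
    seed: int,
    intron_scale: int = 400,
    *,
    tg_len: int = DEFAULT_TG,
    t_len: int = DEFAULT_T,
    contig_name: str = "CFTR_syn",
) -> SyntheticReference:
    """Build the synthetic reference contig.

    Parameters
    ----------
    seed
        Seeds every random choice; identical seeds give byte-identical
        references.
    intron_scale
        Nominal intron length in bases (>= 200 so primer anchors and the
        repeat tract fit between exons).
    tg_len, t_len
        Reference (TG)m(T)n tract composition, default (TG)11(T)7.
    """
    if intron_scale < 200:
        raise ReferenceSizingError(
            f"intron_scale={intron_scale} < 200: no room for primer anchors"
        )
    rng = np.random.default_rng(seed)

    exon_lens = rng.integers(110, 161, size=N_EXONS)
    intron_lens = rng.integers(int(intron_scale * 0.8), int(intron_scale * 1.2) + 1,
                               size=N_EXONS - 1)
    utr = 250

    pieces: list[np.ndarray] = []
    exons: list[Exon] = []
    pos = 0

    def rand_seq(n: int) -> np.ndarray:
        return _BASES[rng.integers(0, 4, size=n)]

    pieces.append(rand_seq(utr))
    pos += utr
    tract_locus: tuple[int, int] | None = None
    for i in range(N_EXONS):
        exons.append(Exon(pos, pos + int(exon_lens[i]), i + 1, LEGACY_EXON_LABELS[i]))
        pieces.append(rand_seq(int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < N_EXONS - 1:
            ilen = int(intron_lens[i])
            if i == 8:  # intron between exons 9 and 10 carries the tract
                tract = "TG" * tg_len + "T" * t_len
                insert = POLYTGT_LEFT_FLANK + tract + POLYTGT_RIGHT_FLANK
                left = (ilen - len(insert)) // 2
                right = ilen - len(insert) - left
                pieces.append(rand_seq(left))
                pieces.append(np.frombuffer(insert.encode(), dtype=np.uint8))
                pieces.append(rand_seq(right))
                tract_start = pos + left + len(POLYTGT_LEFT_FLANK)
                tract_locus = (tract_start, tract_start + len(tract))
            else:
                pieces.append(rand_seq(ilen))
            pos += ilen
    pieces.append(rand_seq(utr))
    pos += utr

    seq = np.concatenate(pieces)
    assert tract_locus is not None
    _ensure_unique(seq, POLYTGT_LEFT_FLANK,
                   tract_locus[0] - len(POLYTGT_LEFT_FLANK))
    _ensure_unique(seq, POLYTGT_RIGHT_FLANK, tract_locus[1])

    gsp2: list[Gsp2Site] = []
    for i, ex in enumerate(exons):
        offf = 30 + int(rng.integers(0, 11))
        offr = 30 + int(rng.integers(0, 11))
        gsp2.append(Gsp2Site(f"E{i + 1:02d}F", ex.start - offf, "+", ex.number))
        gsp2.append(Gsp2Site(f"E{i + 1:02d}R", ex.end + offr, "-", ex.number))
    ts, te = tract_locus
    gsp2.append(Gsp2Site("TGTF", ts - 45, "+", 0))
    gsp2.append(Gsp2Site("TGTR", te + 45, "-", 0))

    e = exons
    breakpoints = [
        BreakpointRecord("CFTRdele2,3", e[1].start - 40, e[2].end + 40, "del",
                         "literature"),
        BreakpointRecord("CFTRdele2-4", e[1].start - 60, e[3].end + 60, "del",
                         "literature"),
        BreakpointRecord("CFTRdele11", e[11].start - 30, e[11].end + 30, "del",
                         "literature"),
        BreakpointRecord("1949del84", e[13].start + 10, e[13].start + 94, "del",
                         "literature"),
        BreakpointRecord("CFTRdele22,23", e[24].start - 30, e[25].end + 30, "del",
                         "literature"),
        BreakpointRecord("CFTRdupe16-18", e[17].start - 50, e[20].end + 50, "dup",
                         "literature"),
    ]

    # breakpoint-targeting primers: the assay design places GSP2s so that
    # reads cross the novel junction of each literature-reported del/dup
    def nearest_exon_number(pos: int) -> int:
        return min(exons, key=lambda ex: abs((ex.start + ex.end) // 2 - pos)).number

    for i, bp in enumerate(breakpoints, start=1):
        extra = [(f"BP{i:02d}F", bp.left - 60, "+"),
                 (f"BP{i:02d}R", bp.right + 60, "-")]
        if bp.type == "dup":
            # tandem junction lies between copies: anchor inside the interval
            extra += [(f"BP{i:02d}Fi", bp.right - 60, "+"),
                      (f"BP{i:02d}Ri", bp.left + 60, "-")]
        for gid, gpos, strand in extra:
            assert 0 <= gpos < len(seq)
            gsp2.append(Gsp2Site(gid, gpos, strand, nearest_exon_number(gpos)))
    gsp2.sort(key=lambda g: g.pos)

    return SyntheticReference(
        contig_name=f"{contig_name}{seed}",
        sequence=seq.tobytes().decode("ascii"),
        exons=exons,
        polytgt_locus=tract_locus,
        gsp2_sites=gsp2,
        breakpoints=breakpoints,
        seed=seed,
    )
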