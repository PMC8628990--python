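"""Haplotype model: a reference sequence plus a set of non-overlapping edits.

Used by the read simulator to (a) build each haplotype's sequence, (b) locate
primer anchors on the haplotype (anchors inside a deletion vanish, anchors
inside a tandem duplication occur twice), and (c) produce SAM-convention
alignments for reads drawn from haplotype coordinates.

Small edits (SNVs, small indels, repeat-tract replacements) appear in read
CIGARs as M/I/D. Structural edits — deletions or tandem duplications of
``STRUCTURAL_MIN`` (50) bases or more — are what a breakpoint-unaware aligner
would soft-clip: a read crossing a structural junction is aligned on the side
carrying most of its bases and soft-clipped on the other, so its sequence
still contains the junction (which the SV caller detects) while SNV/indel
pileups see no giant indel ops.
"""

from __future__ import annotations

import bisect
import dataclasses

import numpy as np

STRUCTURAL_MIN = 50


class CoordinateError(ValueError):
    """An edit lies outside the contig or edits overlap."""


@dataclasses.dataclass(frozen=True)
class Edit:
    """Replace ref[start:end) with ``alt``; for a tandem duplication use
    start == end == insertion point and source=(left, right)."""
    start: int
    end: int
    alt: str = ""
    source: tuple[int, int] | None = None


@dataclasses.dataclass
class _Segment:
    kind: str        # 'M' mapped, 'U' unmapped insertion, 'SI' sourced insertion
    hap_start: int
    hap_end: int
    ref_start: int   # for 'U': insertion point (ref_start == ref_end)
    ref_end: int
    seq: bytes


class Haplotype:
    def __init__(self, ref_seq: str, edits: list[Edit]):
        self.ref_seq = ref_seq
        n = len(ref_seq)
        edits = sorted(edits, key=lambda e: (e.start, e.end))
        prev_end = 0
        for e in edits:
            if not (0 <= e.start <= e.end <= n):
                raise CoordinateError(f"edit {e} outside contig of length {n}")
            if e.start < prev_end:
                raise CoordinateError(f"overlapping edits at {e.start}")
            if e.source is not None and not (
                    0 <= e.source[0] < e.source[1] <= n):
                raise CoordinateError(f"duplication source {e.source} outside contig")
            prev_end = e.end
        self.edits = edits
        self._segments: list[_Segment] = []
        self._build()
        self._hap_starts = [s.hap_start for s in self._segments]

    def _build(self) -> None:
        ref = self.ref_seq
        segs = self._segments
        hap = 0

        def add(kind: str, rs: int, re_: int, seq: str) -> None:
            nonlocal hap
            if not seq and rs == re_:
                return
            segs.append(_Segment(kind, hap, hap + len(seq), rs, re_,
                                 seq.encode("ascii")))
            hap += len(seq)

        cursor = 0
        for e in self.edits:
            if e.start > cursor:
                add("M", cursor, e.start, ref[cursor:e.start])
            if e.source is not None:
                sl, sr = e.source
                add("SI", sl, sr, ref[sl:sr])
            else:
                s, en, alt = e.start, e.end, e.alt
                if len(alt) == en - s:
                    add("M", s, en, alt)          # pure substitution block
                else:
                    p = 0
                    while p < en - s and p < len(alt) and ref[s + p] == alt[p]:
                        p += 1
                    q = 0
                    while (q < en - s - p and q < len(alt) - p
                           and ref[en - 1 - q] == alt[len(alt) - 1 - q]):
                        q += 1
                    if p:
                        add("M", s, s + p, ref[s:s + p])
                    mid = alt[p:len(alt) - q]
                    if mid:
                        add("U", en - q, en - q, mid)
                    # deleted ref bases [s+p, en-q) become a ref gap
                    if q:
                        add("M", en - q, en, ref[en - q:en])
            cursor = e.end
        if cursor < len(ref):
            add("M", cursor, len(ref), ref[cursor:])
        self.hap_len = hap
        self.seq_bytes = b"".join(s.seq for s in segs)
        self.seq_array = np.frombuffer(self.seq_bytes, dtype=np.uint8)

    # -- anchors -----------------------------------------------------------

    def anchor_positions(self, ref_pos: int) -> list[int]:
        """Haplotype coordinates at which reference position ``ref_pos``
        appears (0 if deleted, 2 if tandem-duplicated)."""
        out = []
        for s in self._segments:
            if s.kind in ("M", "SI") and s.ref_start <= ref_pos < s.ref_end:
                out.append(s.hap_start + (ref_pos - s.ref_start))
        return out

    # -- alignment ---------------------------------------------------------

    def align(self, h0: int, h1: int) -> tuple[int, list[tuple[str, int]]] | None:
        """Align haplotype interval [h0, h1) back to the reference.

        Returns (ref_start, cigar) with the sequence fully accounted for by
        M/I/S ops (plus D for small deletions), or None if the interval has
        no mappable bases. Structural junctions split the read; the side with
        more aligned bases is kept and the rest soft-clipped.
        """
        i = bisect.bisect_right(self._hap_starts, h0) - 1
        pieces: list[tuple[str, int, int]] = []  # (op, qlen, ref_start)
        while i < len(self._segments):
            s = self._segments[i]
            if s.hap_start >= h1:
                break
            a = max(h0, s.hap_start)
            b = min(h1, s.hap_end)
            if b > a:
                off = a - s.hap_start
                if s.kind == "U":
                    pieces.append(("I", b - a, -1))
                else:
                    pieces.append(("M", b - a, s.ref_start + off))
            i += 1
        if not any(op == "M" for op, _, _ in pieces):
            return None

        # Insert D/junction tokens between consecutive mapped pieces.
        tokens: list[tuple[str, int, int]] = []  # op in M/I/D/J (J=junction)
        last_ref_end = None
        for op, qlen, rs in pieces:
            if op == "M":
                if last_ref_end is not None:
                    gap = rs - last_ref_end
                    if gap < 0 or gap >= STRUCTURAL_MIN:
                        tokens.append(("J", 0, -1))
                    elif gap > 0:
                        tokens.append(("D", gap, -1))
                last_ref_end = rs + qlen
                tokens.append(("M", qlen, rs))
            else:
                if qlen >= STRUCTURAL_MIN:
                    tokens.append(("J", qlen, -1))
                else:
                    tokens.append(("I", qlen, -1))

        # Split into runs at junctions; keep the run with the most M bases.
        runs: list[list[tuple[str, int, int]]] = [[]]
        for t in tokens:
            if t[0] == "J":
                runs.append([t])   # junction query bases soft-clip with run boundary
                runs.append([])
            else:
                runs[-1].append(t)
        scored = [(sum(q for op, q, _ in r if op == "M"), j)
                  for j, r in enumerate(runs)]
        best = max(scored)[1]
        lead = sum(q for r in runs[:best] for op, q, _ in r if op in "MIJ")
        trail = sum(q for r in runs[best + 1:] for op, q, _ in r if op in "MIJ")
        run = runs[best]
        # trim non-M edges inside the run
        while run and run[0][0] != "M":
            if run[0][0] == "I":
                lead += run[0][1]
            run = run[1:]
        while run and run[-1][0] != "M":
            if run[-1][0] == "I":
                trail += run[-1][1]
            run = run[:-1]
        ref_start = run[0][2]
        cigar: list[tuple[str, int]] = []
        if lead:
            cigar.append(("S", lead))
        for op, q, _ in run:
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + q)
            else:
                cigar.append((op, q))
        if trail:
            cigar.append(("S", trail))
        return ref_start, cigar
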