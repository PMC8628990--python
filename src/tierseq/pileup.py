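"""Evidence extraction from deduplicated fragments.

A :class:`FragmentPileup` walks every fragment consensus alignment once,
collecting candidate variants (mismatches in M blocks, I/D ops — adjacent
indel ops merge into one replacement allele) in normalized form, together
with the molecular evidence the variant-level QC uses: AO (supporting
fragments), UAO (distinct start sites among them) and per-base fragment
depth.

Clustered indels can hide support when a read's alignment represents the
same haplotype differently, so every candidate can additionally be re-counted
against its local candidate haplotype: fragments whose consensus sequence
contains the variant's alt allele with 10 bp of reference context on each
side support the candidate regardless of how their alignment spelled it.
"""

from __future__ import annotations

import bisect
import dataclasses

import numpy as np

from .dedup import DedupFragment, fragment_depth
from .variants import Variant, normalize_variant


@dataclasses.dataclass
class Evidence:
    ao: int = 0
    start_sites: set = dataclasses.field(default_factory=set)

    @property
    def uao(self) -> int:
        return len(self.start_sites)


class FragmentPileup:
    def __init__(self, fragments, ref_seq: str):
        self.ref_seq = ref_seq
        self.ref_arr = np.frombuffer(ref_seq.encode("ascii"), dtype=np.uint8)
        self.fragments: list[DedupFragment] = sorted(
            fragments, key=lambda f: f.consensus.start)
        self._starts = [f.consensus.start for f in self.fragments]
        self.depth = fragment_depth(self.fragments, len(ref_seq))
        self.candidates: dict[Variant, Evidence] = {}
        self._extract()

    # -- candidate extraction ------------------------------------------------

    def _extract(self) -> None:
        for f in self.fragments:
            for v in self._fragment_variants(f.consensus):
                ev = self.candidates.setdefault(v, Evidence())
                ev.ao += 1
                ev.start_sites.add(f.start_site)

    def _fragment_variants(self, read) -> list[Variant]:
        out: list[Variant] = []
        seq = np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)
        q, r = 0, read.start
        pend_del = 0
        pend_ins = ""
        pend_pos = -1

        def flush() -> None:
            nonlocal pend_del, pend_ins, pend_pos
            if pend_del == 0 and not pend_ins:
                return
            p = pend_pos
            if p == 0:
                pend_del = 0; pend_ins = ""; pend_pos = -1
                return
            ref_allele = self.ref_seq[p - 1:p + pend_del]
            alt_allele = self.ref_seq[p - 1] + pend_ins
            if ref_allele != alt_allele:
                out.append(normalize_variant(p - 1, ref_allele, alt_allele,
                                             self.ref_seq))
            pend_del = 0; pend_ins = ""; pend_pos = -1

        for op, n in read.cigar:
            if op == "M":
                flush()
                block = seq[q:q + n]
                refb = self.ref_arr[r:r + n]
                mism = np.nonzero(block != refb)[0]
                for i in mism:
                    out.append(Variant(r + int(i), chr(refb[i]), chr(block[i])))
                q += n
                r += n
            elif op == "I":
                if pend_pos < 0:
                    pend_pos = r
                pend_ins += read.seq[q:q + n]
                q += n
            elif op == "D":
                if pend_pos < 0:
                    pend_pos = r
                pend_del += n
                r += n
            elif op == "S":
                flush()
                q += n
        flush()
        return out

    # -- evidence queries ----------------------------------------------------

    def depth_at(self, pos: int) -> int:
        if 0 <= pos < len(self.depth):
            return int(self.depth[pos])
        return 0

    def _overlapping(self, lo: int, hi: int):
        i = bisect.bisect_left(self._starts, lo - 200)
        for f in self.fragments[i:]:
            if f.consensus.start >= hi:
                break
            if f.consensus.ref_end > lo:
                yield f

    def kmer_recount(self, v: Variant, window: int = 10) -> Evidence:
        """Support for ``v`` by exact match of its local candidate haplotype
        (alt allele with ``window`` bp of reference context on each side)."""
        lo = max(0, v.pos - window)
        hi = min(len(self.ref_seq), v.end + window)
        kmer = self.ref_seq[lo:v.pos] + v.alt + self.ref_seq[v.end:hi]
        ev = Evidence()
        for f in self._overlapping(lo, hi):
            if kmer in f.consensus.seq:
                ev.ao += 1
                ev.start_sites.add(f.start_site)
        return ev

    def evidence_for(self, v: Variant, *, use_kmer: bool = True) -> Evidence:
        ev = self.candidates.get(v, Evidence())
        if use_kmer:
            alt = self.kmer_recount(v)
            if alt.ao > ev.ao:
                return alt
        return ev
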