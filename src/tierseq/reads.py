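"""Lightweight aligned-read records honoring SAM conventions.

The assay is anchored multiplex PCR: every fragment has one end fixed at a
gene-specific primer (GSP2) and the other end set by random fragmentation.
Molecular counting therefore keys on (molecular barcode, random start site,
GSP2). Reads carry the barcode in the ``RX`` tag (and encoded in the read
name so FASTQ-only workflows retain it), the GSP2 id in ``XG``, and the
random start site in ``XS``.

Records are stored in a plain dataclass with 0-based coordinates, CIGAR as a
list of (op, length) with op in ``MIDS``, and the sequence in
reference-forward orientation; pysam handles conversion to and from SAM.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pysam

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass
class AlignedRead:
    name: str
    start: int                      # 0-based leftmost aligned position
    strand: str                     # '+' or '-'
    cigar: list[tuple[str, int]]    # ops in 'M', 'I', 'D', 'S'
    seq: str                        # reference-forward orientation
    barcode: str | None = None
    gsp2_id: str | None = None
    start_site: int | None = None   # random (non-primer) fragment end

    @property
    def ref_end(self) -> int:
        return self.start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def derived_start_site(self) -> int:
        """Fallback molecular start site from the alignment when no XS tag is
        present: the non-primer end (right end for '+' reads, left for '-')."""
        if self.start_site is not None:
            return self.start_site
        return self.ref_end if self.strand == "+" else self.start

    def cigarstring(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    # -- pysam conversion --------------------------------------------------

    def to_pysam(self, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(header)
        a.query_name = self.name
        a.reference_id = 0
        a.reference_start = self.start
        a.flag = 16 if self.strand == "-" else 0
        a.mapping_quality = 60
        a.cigarstring = self.cigarstring()
        a.query_sequence = self.seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(self.seq))
        tags = []
        if self.barcode is not None:
            tags.append(("RX", self.barcode))
        if self.gsp2_id is not None:
            tags.append(("XG", self.gsp2_id))
        if self.start_site is not None:
            tags.append(("XS", self.start_site))
        a.set_tags(tags)
        return a

    @classmethod
    def from_pysam(cls, a: pysam.AlignedSegment) -> "AlignedRead":
        num2op = "MIDNSHP=XB"
        cigar = [(num2op[op], n) for op, n in (a.cigartuples or [])]

        def tag(name):
            return a.get_tag(name) if a.has_tag(name) else None

        return cls(
            name=a.query_name,
            start=a.reference_start,
            strand="-" if a.is_reverse else "+",
            cigar=cigar,
            seq=a.query_sequence or "",
            barcode=tag("RX"),
            gsp2_id=tag("XG"),
            start_site=tag("XS"),
        )


def sam_header(contig_name: str, contig_length: int) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": contig_name, "LN": contig_length}]}
    )


def write_sam(reads: list[AlignedRead], path: str | Path,
              contig_name: str, contig_length: int) -> None:
    header = sam_header(contig_name, contig_length)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            fh.write(r.to_pysam(header))


def read_sam(path: str | Path) -> list[AlignedRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return [AlignedRead.from_pysam(a) for a in fh if not a.is_unmapped]


def write_fastq(reads: list[AlignedRead], path: str | Path) -> None:
    """Reads in sequencing orientation; '-' reads are reverse-complemented."""
    with open(path, "w") as fh:
        for r in reads:
            seq = revcomp(r.seq) if r.strand == "-" else r.seq
            fh.write(f"@{r.name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) pairs."""
    out = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            out.append((rec.name, rec.sequence))
    return out
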