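"""Targeted-mutation file (TMF): the second-tier panel.

The TMF is a VCF listing the exact variant positions and nucleotide changes
whose genotypes (including explicit reference calls) are reported at the
second tier. The default panel mirrors the v1.0.0 composition: 334
CF-causing SNVs/small indels, R117H (a variant of varying clinical
consequence whose severity depends on the polyTG/T tract in cis), and three
pathogenic/likely-pathogenic variants relevant to the screened population —
338 entries in all, placed at synthetic exonic coordinates.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pysam

from .variants import Variant, normalize_variant

CLASSIFICATIONS = ("CF-causing", "VCC", "VOUS", "P", "LP", "LB", "B")

PANEL_VERSION = "v1.0.0"


class TmfParseError(ValueError):
    pass


class TmfValidationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TmfEntry:
    chrom: str
    pos: int            # 1-based, VCF convention
    ref: str
    alt: str
    hgvs_c: str
    legacy_name: str
    classification: str
    variant: Variant    # normalized, 0-based

    def __post_init__(self) -> None:
        assert self.ref != self.alt
        assert self.classification in CLASSIFICATIONS

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _entry(chrom: str, pos0: int, ref: str, alt: str, ref_seq: str,
           hgvs: str = "", legacy: str = "", cls: str = "CF-causing") -> TmfEntry:
    v = normalize_variant(pos0, ref, alt, ref_seq)
    return TmfEntry(chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                    hgvs_c=hgvs or f"c.{pos0 + 1}{ref}>{alt}",
                    legacy_name=legacy, classification=cls, variant=v)


# ---------------------------------------------------------------------------
# VCF round-trip
# ---------------------------------------------------------------------------

def write_tmf(entries: list[TmfEntry], path: str | Path,
              contig: str, contig_length: int,
              version: str = PANEL_VERSION) -> None:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line(f"##tmf_version={version}")
    header.add_line('##INFO=<ID=CLS,Number=1,Type=String,Description='
                    '"Clinical classification">')
    header.add_line('##INFO=<ID=HGVS,Number=1,Type=String,Description='
                    '"HGVS c. name">')
    header.add_line('##INFO=<ID=LEGACY,Number=1,Type=String,Description='
                    '"Legacy name">')
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for e in sorted(entries, key=lambda x: x.pos):
            rec = vf.new_record(contig=e.chrom, start=e.pos - 1,
                                alleles=(e.ref, e.alt))
            rec.info["CLS"] = e.classification
            rec.info["HGVS"] = e.hgvs_c.replace(" ", "_")
            if e.legacy_name:
                rec.info["LEGACY"] = e.legacy_name.replace(" ", "_")
            vf.write(rec)


def load_tmf(path: str | Path, ref_seq: str | None = None) -> list[TmfEntry]:
    """Load and validate a TMF. Duplicate (chrom, pos, ref, alt) records are
    rejected; an empty panel loads with a warning. When ``ref_seq`` is given,
    entries are normalized against it (otherwise taken as already
    left-aligned)."""
    entries: list[TmfEntry] = []
    seen: set[tuple] = set()
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise TmfParseError(f"cannot parse TMF {path}: {exc}") from exc
    with vf:
        for i, rec in enumerate(vf, start=1):
            if not rec.alts:
                raise TmfParseError(f"record {i} at pos {rec.pos} has no ALT")
            ref, alt = rec.ref, rec.alts[0]
            key = (rec.chrom, rec.pos, ref, alt)
            if key in seen:
                raise TmfValidationError(f"duplicate TMF entry {key}")
            seen.add(key)
            if ref_seq is not None:
                v = normalize_variant(rec.start, ref, alt, ref_seq)
            else:
                v = Variant(rec.start, ref, alt)
            def info(key: str, default: str = "") -> str:
                try:
                    return str(rec.info.get(key, default))
                except (KeyError, ValueError):  # tag absent from the header
                    return default

            entries.append(TmfEntry(
                chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                hgvs_c=info("HGVS"), legacy_name=info("LEGACY"),
                classification=info("CLS", "VOUS"), variant=v,
            ))
    if not entries:
        warnings.warn("TMF contains no entries")
    return entries


# ---------------------------------------------------------------------------
# default synthetic panel
# ---------------------------------------------------------------------------

def build_default_panel(ref) -> list[TmfEntry]:
    """The v1.0.0-composition panel on the synthetic contig: 334 CF-causing
    variants (including adjacent F508del/I507del analogs, whose overlapping
    deletions exercise indel-representation handling), R117H, and three
    population-specific P/LP variants. Deterministic given the reference."""
    seq = ref.sequence
    chrom = ref.contig_name
    rng = np.random.default_rng(ref.seed + 104729)

    named: list[TmfEntry] = []
    # adjacent 3-bp deletions in exon 11 (legacy 10), overlapping by one base
    q = ref.exons[10].start + 30
    named.append(_entry(chrom, q, seq[q:q + 4], seq[q], seq,
                        hgvs="c.1521_1523del", legacy="F508del"))
    named.append(_entry(chrom, q - 2, seq[q - 2:q + 2], seq[q - 2], seq,
                        hgvs="c.1519_1521del", legacy="I507del"))
    p = ref.exons[3].start + 40
    named.append(_entry(chrom, p, seq[p], _other_base(seq[p], rng), seq,
                        hgvs="c.350G>A", legacy="R117H", cls="VCC"))
    p = ref.exons[5].start + 20
    named.append(_entry(chrom, p, seq[p], _other_base(seq[p], rng), seq,
                        hgvs="c.653T>A", legacy="L218X", cls="P"))
    p = ref.exons[6].start + 25
    named.append(_entry(chrom, p, seq[p:p + 2], seq[p], seq,
                        hgvs="c.764delT", legacy="896delT", cls="P"))
    p = ref.exons[7].start + 35
    named.append(_entry(chrom, p, seq[p:p + 4], seq[p], seq,
                        hgvs="c.935_937del", legacy="delF311", cls="LP"))

    named_spans = [(e.variant.pos - 6, e.variant.end + 6) for e in named]

    grid: list[int] = []
    for ex in ref.exons:
        pos = ex.start + 6
        while pos <= ex.end - 10:
            if not any(a <= pos < b for a, b in named_spans):
                grid.append(pos)
            pos += 9

    n_cf_named = 2  # F508del, I507del
    need = 334 - n_cf_named
    entries = list(named)
    keys = {e.variant for e in named}
    for pos in grid:
        if len(entries) - len(named) >= need:
            break
        u = rng.random()
        if u < 0.75:
            ref_a = seq[pos]
            alt_a = _other_base(ref_a, rng)
        elif u < 0.90:
            k = int(rng.integers(1, 3))
            ref_a = seq[pos:pos + 1 + k]
            alt_a = seq[pos]
        else:
            k = int(rng.integers(1, 3))
            ref_a = seq[pos]
            alt_a = seq[pos] + "".join(
                "ACGT"[int(rng.integers(0, 4))] for _ in range(k))
        e = _entry(chrom, pos, ref_a, alt_a, seq)
        if e.variant in keys:
            continue
        keys.add(e.variant)
        entries.append(e)
    assert len(entries) == 338, f"panel built with {len(entries)} entries"
    return sorted(entries, key=lambda e: e.pos)


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def entry_by_legacy(panel: list[TmfEntry], legacy: str) -> TmfEntry:
    for e in panel:
        if e.legacy_name == legacy:
            return e
    raise KeyError(legacy)
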