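"""Variant representation and normalization.

All variant comparison in the package happens on normalized (left-aligned,
parsimonious) representations, so that an indel observed in a pileup matches
the same indel written differently in a panel file. Positions are 0-based
internally; 1-based only at VCF boundaries.
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True, order=True)
class Variant:
    pos: int    # 0-based position of the first ref base
    ref: str
    alt: str

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.pos + 1}:{self.ref}>{self.alt}"


def normalize_variant(pos: int, ref: str, alt: str, ref_seq: str) -> Variant:
    """Left-align and make parsimonious against ``ref_seq`` (0-based pos)."""
    if ref == alt:
        raise ValueError("ref and alt identical")
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos == 0:
                break
            pos -= 1
            base = ref_seq[pos]
            ref, alt = base + ref, base + alt
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(pos, ref, alt)


@dataclasses.dataclass
class VariantCall:
    """A genotype call with its molecular evidence.

    AO counts deduplicated fragments supporting the alternate allele, UAO the
    distinct molecular start sites among them, DP the fragment depth at the
    site, AF = AO/DP.
    """
    site: Variant
    genotype: str          # 'ref/ref', 'ref/alt', 'alt/alt', 'no-call'
    DP: int
    AO: int
    UAO: int
    AF: float
    filters: list[str] = dataclasses.field(default_factory=list)
    entry: object = None   # TmfEntry when the site comes from a panel

    def __post_init__(self) -> None:
        assert 0 <= self.AF <= 1 + 1e-9
        assert self.UAO <= self.AO <= self.DP

    @property
    def is_alt(self) -> bool:
        return self.genotype in ("ref/alt", "alt/alt")


@dataclasses.dataclass
class VariantFilters:
    """Variant-level QC: alternate observations (AO), unique-start alternate
    observations (UAO), allele fraction (AF), and a minimum depth below which
    the site is a no-call (low-depth regions reflex to orthogonal sequencing).
    The AF floor shipped at 0.3 and was relaxed to 0.2; both are supported."""
    min_ao: int = 5
    min_uao: int = 3
    min_af: float = 0.2
    min_dp: int = 10
    hom_af: float = 0.8


LEGACY_FILTERS = VariantFilters(min_af=0.3)
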