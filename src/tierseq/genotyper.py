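"""Second-tier targeted genotyping at panel (TMF) positions.

The second tier never unblinds off-panel variants: it reports exactly one
genotype per panel entry — explicit reference calls included — from the
deduplicated fragment evidence. A variant is reported when AO >= 5,
UAO >= 3 and AF >= 0.2 (the shipped AF floor; 0.3 was the original default
and remains available via ``LEGACY_FILTERS``). Zygosity uses an AF boundary
of 0.8 for homozygous alternate. Sites below 10 fragments of depth are
no-calls, matching the depth at which regions reflex to orthogonal
sequencing.
"""

from __future__ import annotations

from .panel import TmfEntry
from .pileup import FragmentPileup
from .variants import VariantCall, VariantFilters


def genotype_site(
    entry: TmfEntry,
    pileup: FragmentPileup,
    filters: VariantFilters = VariantFilters(),
) -> VariantCall:
    v = entry.variant
    dp = pileup.depth_at(v.pos)
    if dp < filters.min_dp:
        return VariantCall(site=v, genotype="no-call", DP=dp, AO=0, UAO=0,
                           AF=0.0, filters=["low_depth"], entry=entry)
    ev = pileup.evidence_for(v, use_kmer=False)

    def failures(e) -> list[str]:
        failed = []
        if e.ao < filters.min_ao:
            failed.append(f"AO<{filters.min_ao}")
        if e.uao < filters.min_uao:
            failed.append(f"UAO<{filters.min_uao}")
        if e.ao / dp < filters.min_af:
            failed.append(f"AF<{filters.min_af}")
        return failed

    failed = failures(ev)
    if failed and ev.ao >= filters.min_uao:
        # supported but filtered: re-evaluate against the candidate haplotype
        # in case alignment representation hid part of the support
        ev2 = pileup.evidence_for(v, use_kmer=True)
        if ev2.ao > ev.ao:
            ev = ev2
            failed = failures(ev)
    ao = min(ev.ao, dp)
    af = ao / dp
    if failed:
        # evidence present but filtered: an explicit reference call carrying
        # the failed criteria, so the pre-change AF policy is reproducible
        return VariantCall(site=v, genotype="ref/ref", DP=dp, AO=ao,
                           UAO=min(ev.uao, ao), AF=af,
                           filters=failed if ao > 0 else [], entry=entry)
    genotype = "alt/alt" if af >= filters.hom_af else "ref/alt"
    return VariantCall(site=v, genotype=genotype, DP=dp, AO=ao,
                       UAO=min(ev.uao, ao), AF=af, entry=entry)


def genotype_panel(
    panel: list[TmfEntry],
    pileup: FragmentPileup,
    filters: VariantFilters = VariantFilters(),
) -> list[VariantCall]:
    """One call per panel entry, in panel order (bijective with the TMF)."""
    return [genotype_site(e, pileup, filters) for e in panel]
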