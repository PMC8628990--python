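"""Third-tier deletion/duplication detection.

Two complementary detectors, mirroring how targeted assays find exon-scale
del/dup:

* **SV path** — breakpoint-targeted: a database of recurrent rearrangements
  with literature-reported breakpoints is screened for junction-supporting
  reads (reads whose sequence contains the novel junction k-mer). Precise,
  but blind to events without a database breakpoint.
* **CNV path** — panel-of-normals molecular counting: per-GSP2 unique
  fragment counts, normalized for library size, are compared to the median of
  a normal cohort; a GSP2 is flagged when its ratio crosses the deletion
  (<= 0.6) or amplification (>= 1.3) threshold with a z-test p <= 0.05
  against the normals' log-ratio spread. Breakpoint-free but exon-resolution
  only, and weak on small events.

``combine`` unions the two; every call stays ``validated=False`` until qPCR
confirmation reconciles it (see :mod:`tierseq.qpcr`).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass(frozen=True)
class BreakpointRecord:
    name: str
    left: int
    right: int
    type: str           # 'del' or 'dup'
    source: str = ""

    def __post_init__(self) -> None:
        assert self.left < self.right
        assert self.type in ("del", "dup")


def load_breakpoints(path: str | Path) -> list[BreakpointRecord]:
    df = pd.read_csv(path, sep="\t")
    recs = [BreakpointRecord(str(r["name"]), int(r["left"]), int(r["right"]),
                             str(r["type"]), str(r.get("source", "")))
            for _, r in df.iterrows()]
    names = [r.name for r in recs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate breakpoint names")
    return recs


@dataclasses.dataclass
class DelDupCall:
    interval: tuple[int, int]
    type: str                       # 'del' or 'dup'
    exon_first: int                 # sequential exon numbers spanned
    exon_last: int
    exon_label: str                 # e.g. 'exons 2-3 (2-3)'
    copy_ratio: float | None = None
    junction_reads: int | None = None
    p_value: float | None = None
    evidence: str = "SV"            # 'SV', 'CNV', 'both'
    validated: bool = False
    low_confidence: bool = False
    name: str | None = None

    def overlaps(self, other: "DelDupCall") -> bool:
        return (self.type == other.type
                and self.interval[0] < other.interval[1]
                and other.interval[0] < self.interval[1])


def _exon_span(ref, start: int, end: int) -> tuple[int, int, str]:
    touched = [e for e in ref.exons if e.start < end and start < e.end]
    if not touched:
        touched = [ref.exon_for_position((start + end) // 2)]
    first, last = touched[0], touched[-1]
    seq = (str(first.number) if first is last
           else f"{first.number}-{last.number}")
    leg = (first.legacy if first is last else f"{first.legacy}-{last.legacy}")
    label = f"exons {seq}" + (f" ({leg})" if leg != seq else "")
    return first.number, last.number, label


# ---------------------------------------------------------------------------
# SV path
# ---------------------------------------------------------------------------

def junction_kmer(ref_seq: str, bp: BreakpointRecord, flank: int = 12) -> str:
    """The novel sequence created by the rearrangement: for a deletion the
    bases flanking the removed interval become adjacent; for a tandem
    duplication the end of the copy abuts its own start."""
    if bp.type == "del":
        return ref_seq[bp.left - flank:bp.left] + ref_seq[bp.right:bp.right + flank]
    return ref_seq[bp.right - flank:bp.right] + ref_seq[bp.left:bp.left + flank]


def sv_call(
    fragments,
    breakpoint_db: list[BreakpointRecord],
    ref,
    *,
    flank: int = 12,
    min_start_sites: int = 3,
) -> list[DelDupCall]:
    """Breakpoint-targeted SV calling on deduplicated fragments.

    A fragment supports a database event when its consensus sequence contains
    the event's junction k-mer. A call requires support from at least
    ``min_start_sites`` distinct molecular start sites; events without a
    database breakpoint are never emitted by this path.
    """
    ref_seq = ref.sequence
    calls = []
    for bp in breakpoint_db:
        kmer = junction_kmer(ref_seq, bp, flank)
        support = [f for f in fragments if kmer in f.consensus.seq]
        sites = {(f.consensus.derived_start_site(), f.consensus.strand)
                 for f in support}
        if len(sites) >= min_start_sites:
            first, last, label = _exon_span(ref, bp.left, bp.right)
            calls.append(DelDupCall(
                interval=(bp.left, bp.right), type=bp.type,
                exon_first=first, exon_last=last, exon_label=label,
                junction_reads=len(support), evidence="SV", name=bp.name,
            ))
    return calls


# ---------------------------------------------------------------------------
# CNV path
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CnvPolicy:
    amp_threshold: float = 1.3
    del_threshold: float = 0.6
    p_threshold: float = 0.05
    min_gsp2: int = 2          # events on fewer flagged GSP2s are low-confidence
    max_gap: int = 1           # unflagged GSP2s bridged when merging
    sd_floor: float = 0.05     # log2 units; guards degenerate normals


def cnv_ratios(
    sample_counts: pd.Series,
    normals: pd.DataFrame,
    *,
    sd_floor: float = 0.05,
) -> pd.DataFrame:
    """Per-GSP2 copy ratios and z-test p-values against the normals.

    Columns are normalized by their totals (library size), the per-GSP2
    reference level is the normals' median, and the p-value is a two-sided
    one-sample z of the sample's log2 ratio against the normals' log2-ratio
    spread (no multiple-testing correction; the 0.05 threshold is applied
    raw). GSP2s whose normal median is zero are masked (ratio NaN).
    """
    normals = normals.loc[sample_counts.index]
    norm_n = normals / normals.sum(axis=0)
    samp = sample_counts / sample_counts.sum()
    med = norm_n.median(axis=1)
    masked = med <= 0
    if masked.any():
        warnings.warn(f"{int(masked.sum())} GSP2(s) with zero normal median masked")
    med_safe = med.where(~masked, np.nan)
    ratio = samp / med_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        log_norm = np.log2(norm_n.div(med_safe, axis=0))
        log_samp = np.log2(ratio.replace(0, np.nan))
    mu = log_norm.mean(axis=1)
    sd = log_norm.std(axis=1, ddof=1).fillna(0.0).clip(lower=sd_floor)
    z = (log_samp - mu) / sd
    # ratio 0 (full dropout) is maximally significant
    z = z.where(ratio > 0, -np.inf)
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=ratio.index)
    p = p.where(~masked, np.nan)
    return pd.DataFrame({"ratio": ratio, "p_value": p})


def cnv_call(
    sample_counts: pd.Series,
    normals: pd.DataFrame,
    ref,
    policy: CnvPolicy = CnvPolicy(),
    *,
    exclude_gsp2: tuple[str, ...] = (),
) -> list[DelDupCall]:
    """Panel-of-normals CNV calling at GSP2 resolution, merged to exon-level
    calls. GSP2s on the exclusion list (recurrent-artifact primers) never
    contribute. Breakpoints are reported at exon resolution only."""
    table = cnv_ratios(sample_counts, normals, sd_floor=policy.sd_floor)
    order = sorted(table.index, key=lambda g: ref.gsp2_by_id(g).pos)
    table = table.loc[order]

    def direction(g: str) -> str | None:
        if g in exclude_gsp2:
            return None
        r, p = table.at[g, "ratio"], table.at[g, "p_value"]
        if not np.isfinite(p) or p > policy.p_threshold or not np.isfinite(r):
            return None
        if r <= policy.del_threshold:
            return "del"
        if r >= policy.amp_threshold:
            return "dup"
        return None

    dirs = [direction(g) for g in order]
    calls: list[DelDupCall] = []
    i = 0
    while i < len(order):
        if dirs[i] is None:
            i += 1
            continue
        kind = dirs[i]
        group = [i]
        j = i + 1
        gap = 0
        while j < len(order):
            if dirs[j] == kind:
                group.append(j)
                gap = 0
            elif dirs[j] is None and gap < policy.max_gap:
                gap += 1
            else:
                break
            j += 1
        sites = [ref.gsp2_by_id(order[k]) for k in group]
        lo = min(s.pos for s in sites)
        hi = max(s.pos for s in sites) + 1
        first, last, label = _exon_span(ref, lo, hi)
        ratios = [table.at[order[k], "ratio"] for k in group]
        pvals = [table.at[order[k], "p_value"] for k in group]
        calls.append(DelDupCall(
            interval=(lo, hi), type=kind,
            exon_first=first, exon_last=last, exon_label=label,
            copy_ratio=float(np.mean(ratios)), p_value=float(np.min(pvals)),
            evidence="CNV", low_confidence=len(group) < policy.min_gsp2,
        ))
        i = group[-1] + 1
    return calls


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def combine(sv_calls: list[DelDupCall], cnv_calls: list[DelDupCall]) -> list[DelDupCall]:
    """Union the two evidence paths; overlapping same-type calls merge into a
    single call with evidence='both' (keeping the SV interval, which is
    breakpoint-precise). All calls remain validated=False until qPCR."""
    out: list[DelDupCall] = []
    used_cnv: set[int] = set()
    for sv in sv_calls:
        merged = dataclasses.replace(sv, validated=False)
        for j, cnv in enumerate(cnv_calls):
            if j not in used_cnv and sv.overlaps(cnv):
                merged = dataclasses.replace(
                    merged, evidence="both", copy_ratio=cnv.copy_ratio,
                    p_value=cnv.p_value,
                )
                used_cnv.add(j)
        out.append(merged)
    for j, cnv in enumerate(cnv_calls):
        if j not in used_cnv:
            out.append(dataclasses.replace(cnv, validated=False))
    return out
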