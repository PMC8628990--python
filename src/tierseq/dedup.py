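"""Molecular-barcode deduplication, sample-level QC, and coverage reporting.

A sequenced molecule is identified by its barcode, its random fragmentation
end (the "start site"), and the GSP2 primer that anchored it; PCR/optical
copies collapse into one :class:`DedupFragment` whose consensus is a
per-column majority vote (ties resolve to the reference base). Sample-level
QC follows the assay's gates: unique fragment total >= 20,000 and average
unique start sites per GSP2 >= 30, both inclusive.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter, defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from .reads import AlignedRead


@dataclasses.dataclass
class DedupFragment:
    barcode: str
    start_site: tuple[int, str]
    gsp2_id: str | None
    read_count: int
    consensus: AlignedRead

    def __post_init__(self) -> None:
        assert self.read_count >= 1


@dataclasses.dataclass
class DedupResult:
    fragments: list[DedupFragment]
    dropped_missing_barcode: int

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


def _infer_gsp2(read: AlignedRead, gsp2_sites) -> str | None:
    """Nearest same-strand anchor to the primer-fixed end of the read."""
    primer_end = read.start if read.strand == "+" else read.ref_end - 1
    best, best_d = None, None
    for g in gsp2_sites:
        if g.strand != read.strand:
            continue
        d = abs(g.pos - primer_end)
        if best_d is None or d < best_d:
            best, best_d = g.gsp2_id, d
    return best


def _column_ref_positions(read: AlignedRead) -> np.ndarray:
    """Reference position for each query column; -1 for I/S columns."""
    out = np.full(read.query_length, -1, dtype=np.int64)
    q = 0
    r = read.start
    for op, n in read.cigar:
        if op == "M":
            out[q:q + n] = np.arange(r, r + n)
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op == "D":
            r += n
    return out


def deduplicate(
    alignments: list[AlignedRead],
    reference: str,
    *,
    gsp2_sites=None,
) -> DedupResult:
    """Collapse reads into unique molecules keyed by
    (barcode, start site, strand, GSP2).

    Reads without a barcode tag are excluded with a warning and counted in
    the drop report. When a read carries no GSP2 tag and ``gsp2_sites`` is
    given, membership is inferred from the nearest same-strand anchor.
    """
    groups: dict[tuple, list[AlignedRead]] = defaultdict(list)
    dropped = 0
    for r in alignments:
        if r.barcode is None:
            dropped += 1
            continue
        gsp2 = r.gsp2_id
        if gsp2 is None and gsp2_sites is not None:
            gsp2 = _infer_gsp2(r, gsp2_sites)
        key = (r.barcode, r.derived_start_site(), r.strand, gsp2)
        groups[key].append(r)
    if dropped:
        warnings.warn(f"{dropped} read(s) without barcode tag excluded")

    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    fragments: list[DedupFragment] = []
    for (bc, site, strand, gsp2), reads in groups.items():
        if len(reads) == 1:
            cons = reads[0]
        else:
            # consensus over reads sharing the modal alignment
            modal = Counter((r.start, r.cigarstring()) for r in reads).most_common(1)[0][0]
            sub = [r for r in reads if (r.start, r.cigarstring()) == modal]
            arrs = np.vstack([
                np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8) for r in sub
            ])
            cons_arr = arrs[0].copy()
            disagree = np.nonzero((arrs != arrs[0]).any(axis=0))[0]
            if disagree.size:
                colref = _column_ref_positions(sub[0])
                for c in disagree:
                    vals, counts = np.unique(arrs[:, c], return_counts=True)
                    top = counts.max()
                    winners = vals[counts == top]
                    if len(winners) == 1:
                        cons_arr[c] = winners[0]
                    elif colref[c] >= 0 and ref_arr[colref[c]] in winners:
                        cons_arr[c] = ref_arr[colref[c]]
                    else:
                        cons_arr[c] = winners.min()
            cons = dataclasses.replace(
                sub[0], seq=cons_arr.tobytes().decode("ascii"),
                name=sub[0].name.rsplit(".", 1)[0],
            )
        fragments.append(DedupFragment(
            barcode=bc, start_site=(site, strand), gsp2_id=gsp2,
            read_count=len(reads), consensus=cons,
        ))
    return DedupResult(fragments=fragments, dropped_missing_barcode=dropped)


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SampleQcMetrics:
    unique_fragment_total: int
    avg_unique_start_sites_per_gsp2: float
    deduplicated_mean_coverage: float


@dataclasses.dataclass
class QcPolicy:
    min_unique_fragments: int = 20000
    min_avg_start_sites: float = 30.0


@dataclasses.dataclass
class QcResult:
    passed: bool
    reasons: list[str]


def compute_sample_metrics(
    fragments: list[DedupFragment],
    roi: list[tuple[int, int]],
) -> SampleQcMetrics:
    per_gsp2: dict[str | None, set] = defaultdict(set)
    for f in fragments:
        per_gsp2[f.gsp2_id].add(f.start_site)
    avg_sites = (float(np.mean([len(s) for s in per_gsp2.values()]))
                 if per_gsp2 else 0.0)
    rep = coverage_report(fragments, roi)
    return SampleQcMetrics(
        unique_fragment_total=len(fragments),
        avg_unique_start_sites_per_gsp2=avg_sites,
        deduplicated_mean_coverage=rep.mean_depth,
    )


def sample_qc(metrics: SampleQcMetrics, policy: QcPolicy = QcPolicy()) -> QcResult:
    """Pass iff both thresholds are met (inclusive). Failures list every
    violated criterion."""
    reasons = []
    if metrics.unique_fragment_total < policy.min_unique_fragments:
        reasons.append(
            f"unique fragment total {metrics.unique_fragment_total} "
            f"< {policy.min_unique_fragments}"
        )
    if metrics.avg_unique_start_sites_per_gsp2 < policy.min_avg_start_sites:
        reasons.append(
            f"average unique start sites per GSP2 "
            f"{metrics.avg_unique_start_sites_per_gsp2:.1f} "
            f"< {policy.min_avg_start_sites}"
        )
    return QcResult(passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoverageReport:
    mean_depth: float
    uniformity_pct: float
    low_regions: list[tuple[int, int]]   # maximal disjoint runs with depth < 10
    roi: list[tuple[int, int]]
    depths: list[np.ndarray]             # per-base depth, one array per roi interval

    def write_bedgraph(self, path: str | Path, contig: str) -> None:
        with open(path, "w") as fh:
            for (s, _e), d in zip(self.roi, self.depths):
                i = 0
                while i < len(d):
                    j = i
                    while j < len(d) and d[j] == d[i]:
                        j += 1
                    fh.write(f"{contig}\t{s + i}\t{s + j}\t{int(d[i])}\n")
                    i = j


def fragment_depth(fragments, length: int) -> np.ndarray:
    """Deduplicated per-base depth over the reference (M/D extents)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for f in fragments:
        c = f.consensus
        diff[c.start] += 1
        diff[min(c.ref_end, length)] -= 1
    return np.cumsum(diff)[:length]


def summarize_depth(
    roi: list[tuple[int, int]],
    depths: list[np.ndarray],
    *,
    uniformity_fraction: float = 0.8,
    low_threshold: int = 10,
) -> CoverageReport:
    """Coverage statistics per the assay's definitions: uniformity is the
    percentage of ROI bases at or above (mean depth - 20%), i.e. 0.8x mean,
    and low regions are maximal runs below 10x (reflexed to orthogonal
    sequencing rather than failing the sample)."""
    all_d = np.concatenate(depths) if depths else np.array([], dtype=np.int64)
    if all_d.size == 0:
        raise ValueError("empty region of interest")
    mean = float(all_d.mean())
    thresh = uniformity_fraction * mean
    uniformity = 100.0 * float((all_d >= thresh).sum()) / all_d.size
    low: list[tuple[int, int]] = []
    for (s, _e), d in zip(roi, depths):
        mask = d < low_threshold
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j < len(mask) and mask[j]:
                    j += 1
                low.append((s + i, s + j))
                i = j
            else:
                i += 1
    return CoverageReport(mean_depth=mean, uniformity_pct=uniformity,
                          low_regions=low, roi=list(roi), depths=depths)


def coverage_report(
    fragments,
    roi: list[tuple[int, int]],
    *,
    contig_length: int | None = None,
) -> CoverageReport:
    if not roi:
        raise ValueError("empty region of interest")
    frags = list(fragments)
    if contig_length is None:
        contig_length = max([max(e for _s, e in roi)]
                            + [f.consensus.ref_end for f in frags])
    depth = fragment_depth(frags, contig_length)
    depths = [depth[s:e].copy() for s, e in roi]
    return summarize_depth(roi, depths)


def gsp2_fragment_counts(fragments, gsp2_ids: list[str]) -> pd.Series:
    """Unique-fragment count per GSP2, the unit at which CNVs are assessed."""
    c = Counter(f.gsp2_id for f in fragments)
    return pd.Series([c.get(g, 0) for g in gsp2_ids], index=gsp2_ids, dtype=float)
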