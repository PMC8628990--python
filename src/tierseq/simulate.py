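"""Synthetic sample generator: the wet lab, in silico.

``simulate_sample`` emulates an anchored-multiplex-PCR library from one
infant's DNA: every fragment has one end fixed at a gene-specific primer
(GSP2), the other end set by random fragmentation (the molecular "start
site"), a 12-mer molecular barcode, and PCR duplicates with independent
per-base sequencing errors. Planted SNVs/indels, exon-scale del/dup (with or
without a known junction) and the intron 9 polyTG/T diplotype are encoded on
two haplotypes, so heterozygous variants land at an expected allele fraction
of 0.5 and a single-copy deletion halves unique coverage on the affected
GSP2s.

Also here: the panel-of-normals coverage matrix, qPCR plates following the
2^-ddCt model, and daily IRT populations for the triage gate. Everything is
deterministic given its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .haplotype import CoordinateError, Edit, Haplotype
from .reads import AlignedRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i

#: Population haplotype frequencies for the (TG)m(T)n tract, keyed (tg, t).
#: 7T on an 11TG background dominates, 9T and 5T are the common minor alleles.
POLYTGT_POPULATION_FREQS: dict[tuple[int, int], float] = {
    (11, 7): 0.57,
    (10, 7): 0.20,
    (12, 7): 0.07,
    (10, 9): 0.09,
    (11, 9): 0.02,
    (12, 5): 0.035,
    (11, 5): 0.015,
}


def draw_polytgt_diplotype(rng: np.random.Generator) -> tuple[tuple[int, int], tuple[int, int]]:
    haps = list(POLYTGT_POPULATION_FREQS)
    p = np.array(list(POLYTGT_POPULATION_FREQS.values()))
    p = p / p.sum()
    i, j = rng.choice(len(haps), size=2, p=p)
    return haps[int(i)], haps[int(j)]


@dataclasses.dataclass(frozen=True)
class PlantedVariant:
    pos: int          # 0-based
    ref: str
    alt: str
    zygosity: str     # 'het' or 'hom'

    def __post_init__(self) -> None:
        assert self.zygosity in ("het", "hom")


@dataclasses.dataclass(frozen=True)
class PlantedDelDup:
    start: int
    end: int
    copy_change: int              # -1 deletion, +1 duplication (heterozygous)
    has_known_breakpoint: bool
    name: str | None = None

    def __post_init__(self) -> None:
        assert self.copy_change in (-1, +1)


@dataclasses.dataclass
class SampleTruth:
    """Ground truth for one simulated infant; houses what parameter-recovery
    tests compare against."""
    sample_id: str
    planted_snv_indels: list[PlantedVariant] = dataclasses.field(default_factory=list)
    planted_deldups: list[PlantedDelDup] = dataclasses.field(default_factory=list)
    polytgt_diplotype: tuple[tuple[int, int], tuple[int, int]] = ((11, 7), (11, 7))
    target_unique_fragments: int = 24000
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for (tg, t) in self.polytgt_diplotype:
            assert 4 <= tg <= 14 and 1 <= t <= 13


@dataclasses.dataclass
class SimulatedSample:
    sample_id: str
    reads: list[AlignedRead]
    contig_name: str
    contig_length: int
    truth: SampleTruth

    def write_sam(self, path) -> None:
        from .reads import write_sam
        write_sam(self.reads, path, self.contig_name, self.contig_length)

    def write_fastq(self, path) -> None:
        from .reads import write_fastq
        write_fastq(self.reads, path)


def _haplotype_edits(ref, truth: SampleTruth) -> list[list[Edit]]:
    ts, te = ref.polytgt_locus
    edits: list[list[Edit]] = [[], []]
    for h, (tg, t) in enumerate(truth.polytgt_diplotype):
        motif = "TG" * tg + "T" * t
        if motif != ref.sequence[ts:te]:
            edits[h].append(Edit(ts, te, motif))
    het_idx = 0
    n = len(ref.sequence)
    for pv in truth.planted_snv_indels:
        if not (0 <= pv.pos and pv.pos + len(pv.ref) <= n):
            raise CoordinateError(f"variant at {pv.pos} outside contig")
        if ref.sequence[pv.pos:pv.pos + len(pv.ref)] != pv.ref:
            raise CoordinateError(f"ref allele mismatch at {pv.pos}")
        e = Edit(pv.pos, pv.pos + len(pv.ref), pv.alt)
        if pv.zygosity == "hom":
            edits[0].append(e)
            edits[1].append(e)
        else:
            edits[het_idx % 2].append(e)
            het_idx += 1
    dd_idx = 0
    for dd in truth.planted_deldups:
        if not (0 <= dd.start < dd.end <= n):
            raise CoordinateError(f"del/dup {dd.start}-{dd.end} outside contig")
        if dd.copy_change == -1:
            e = Edit(dd.start, dd.end, "")
        else:
            e = Edit(dd.end, dd.end, "", source=(dd.start, dd.end))
        edits[(het_idx + dd_idx) % 2].append(e)
        dd_idx += 1
    return edits


def simulate_sample(
    ref,
    truth: SampleTruth,
    *,
    frag_len_range: tuple[int, int] = (120, 181),
    duplication_rate: float = 0.3,
) -> SimulatedSample:
    """Generate barcoded reads and their alignments for one sample.

    Unique fragments per GSP2 anchor per haplotype copy are Poisson with a
    mean set so the expected unique-fragment total matches
    ``truth.target_unique_fragments``. Each unique fragment yields
    ``1 + Poisson(duplication_rate)`` reads sharing barcode and coordinates,
    with independent sequencing errors.
    """
    rng = np.random.default_rng(truth.seed)
    haps = [Haplotype(ref.sequence, e) for e in _haplotype_edits(ref, truth)]

    # anchor occurrences: (hap, gsp2, strand, hap position)
    occ: list[tuple[int, str, str, int]] = []
    for hi, hap in enumerate(haps):
        for g in ref.gsp2_sites:
            for hp in hap.anchor_positions(g.pos):
                occ.append((hi, g.gsp2_id, g.strand, hp))
    mean_per_occ = truth.target_unique_fragments / len(occ)
    frag_counts = rng.poisson(mean_per_occ, size=len(occ))
    n_frag = int(frag_counts.sum())

    lens = rng.integers(frag_len_range[0], frag_len_range[1], size=n_frag)
    bc_idx = rng.integers(0, 4, size=(n_frag, 12))
    barcodes = [_BASES[row].tobytes().decode("ascii") for row in bc_idx]
    n_copies = 1 + rng.poisson(duplication_rate, size=n_frag)

    reads: list[AlignedRead] = []
    fi = 0
    for (hi, gsp2_id, strand, hp), k in zip(occ, frag_counts):
        hap = haps[hi]
        for _ in range(int(k)):
            L = int(lens[fi])
            if strand == "+":
                a, b = hp, min(hp + L, hap.hap_len)
            else:
                a, b = max(0, hp + 1 - L), hp + 1
            aln = hap.align(a, b)
            if aln is None or b <= a:
                fi += 1
                continue
            ref_start, cigar = aln
            template = hap.seq_array[a:b]
            ref_end = ref_start + sum(x for op, x in cigar if op in "MD")
            start_site = ref_end if strand == "+" else ref_start
            bc = barcodes[fi]
            for ci in range(int(n_copies[fi])):
                if truth.error_rate > 0:
                    n_err = rng.binomial(len(template), truth.error_rate)
                else:
                    n_err = 0
                if n_err:
                    seq_arr = template.copy()
                    pos = rng.integers(0, len(template), size=n_err)
                    shift = rng.integers(1, 4, size=n_err)
                    seq_arr[pos] = _BASES[(_BASE_IDX[seq_arr[pos]] + shift) % 4]
                    seq = seq_arr.tobytes().decode("ascii")
                else:
                    seq = template.tobytes().decode("ascii")
                reads.append(AlignedRead(
                    name=f"{truth.sample_id}.{fi:06d}.{ci}_{bc}",
                    start=ref_start, strand=strand, cigar=list(cigar),
                    seq=seq, barcode=bc, gsp2_id=gsp2_id,
                    start_site=int(start_site),
                ))
            fi += 1

    return SimulatedSample(
        sample_id=truth.sample_id, reads=reads,
        contig_name=ref.contig_name, contig_length=len(ref.sequence),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# panel of normals
# ---------------------------------------------------------------------------

def simulate_normals(
    ref,
    n_samples: int,
    seed: int,
    *,
    mean_fragments: int = 24000,
    sample_sigma: float = 0.15,
    count_noise: bool = True,
) -> pd.DataFrame:
    """Per-GSP2 unique-fragment counts for a cohort of del/dup-free normals.

    Each sample has a lognormal library-size scale (sigma ``sample_sigma`` in
    natural log units); counts are Poisson around the scaled per-GSP2 mean.
    ``sample_sigma=0, count_noise=False`` gives the noise-free matrix used to
    characterize the ratio estimator.
    """
    if n_samples < 8:
        raise ValueError("a panel of normals needs at least 8 samples")
    rng = np.random.default_rng(seed)
    gsp2_ids = ref.gsp2_ids
    base = mean_fragments / len(gsp2_ids)
    scales = (np.exp(rng.normal(0.0, sample_sigma, size=n_samples))
              if sample_sigma > 0 else np.ones(n_samples))
    lam = base * scales[None, :] * np.ones((len(gsp2_ids), 1))
    counts = rng.poisson(lam) if count_noise else np.round(lam).astype(int)
    return pd.DataFrame(counts, index=gsp2_ids,
                        columns=[f"N{j + 1:02d}" for j in range(n_samples)])


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr_plate(
    copy_numbers: dict[str, int],
    seed: int,
    *,
    sigma: float = 0.05,
    sample_id: str = "S1",
    control_target: str = "CTRL",
    n_replicates: int = 3,
):
    """Triplicate Ct table for one test sample plus three 2-copy calibrators
    and a no-template control.

    dCt for a target shifts by -log2(copies/2) relative to a 2-copy
    calibrator, plus Gaussian well noise of standard deviation ``sigma``
    (cycles). Zero copies amplify at the background floor (Ct 38).
    """
    from .qpcr import QpcrPlate

    for c in copy_numbers.values():
        if c not in (0, 1, 2, 3, 4):
            raise ValueError("copies must be in 0..4")
    rng = np.random.default_rng(seed)
    base_ct = 25.0
    base_dct = 5.0
    cal_ids = ["CAL1", "CAL2", "CAL3"]
    ntc_id = "NTC"
    rows = []

    def noise() -> float:
        return float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0

    for sid in [sample_id, *cal_ids]:
        offset = float(rng.normal(0.0, 0.3))  # DNA input; cancels in dCt
        for rep in range(n_replicates):
            rows.append((sid, control_target, rep, base_ct + offset + noise()))
        for target in copy_numbers:
            copies = copy_numbers[target] if sid == sample_id else 2
            for rep in range(n_replicates):
                if copies == 0:
                    ct = 38.0 + noise()
                else:
                    ct = (base_ct + base_dct + offset
                          - float(np.log2(copies / 2)) + noise())
                rows.append((sid, target, rep, ct))
    for target in [control_target, *copy_numbers]:
        for rep in range(n_replicates):
            rows.append((ntc_id, target, rep, np.nan))

    wells = pd.DataFrame(rows, columns=["sample_id", "target_id", "replicate", "ct"])
    return QpcrPlate(wells=wells, calibrator_ids=cal_ids, ntc_id=ntc_id,
                     control_target=control_target)


# ---------------------------------------------------------------------------
# first-tier IRT population
# ---------------------------------------------------------------------------

def simulate_irt_population(
    n_days: int,
    per_day: int,
    seed: int,
    *,
    median_ng_ml: float = 21.5,
    log_sigma: float = 0.548,
    start_date: str = "2020-01-01",
) -> pd.DataFrame:
    """Daily IRT draws from a lognormal population.

    The defaults put the daily 95th percentile near 53 ng/mL and the 99.9th
    percentile near 117 ng/mL, the scale on which first-tier screening
    operates.
    """
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    rows = []
    k = 0
    for d in dates:
        irt = median_ng_ml * np.exp(rng.normal(0.0, log_sigma, size=per_day))
        for v in irt:
            rows.append((f"I{k:06d}", d.date().isoformat(), float(v)))
            k += 1
    return pd.DataFrame(rows, columns=["infant_id", "collection_date", "irt_ng_ml"])
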