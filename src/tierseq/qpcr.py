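"""Confirmatory qPCR copy-number analysis (relative quantitation, 2^-ddCt).

Every NGS del/dup call is confirmed by exon-targeted qPCR before reporting.
Each assay runs in triplicate with a reference-gene control target in the
same reaction and three 2-copy calibrator samples per run: dCt = Ct(target)
- Ct(control) per sample, ddCt = dCt - median calibrator dCt, RQ = 2^-ddCt.
RQ maps to a copy number through conservative, configurable ranges; anything
in a gap is equivocal and retested. ``reconcile`` then validates or drops
the NGS calls.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .deldup import DelDupCall


class RunInvalidError(ValueError):
    """No-template control amplified: the run cannot be interpreted."""


NTC_CT_FLOOR = 35.0


@dataclasses.dataclass
class QpcrPlate:
    wells: pd.DataFrame               # sample_id, target_id, replicate, ct
    calibrator_ids: list[str]
    ntc_id: str
    control_target: str

    def validate(self) -> None:
        ntc = self.wells[self.wells.sample_id == self.ntc_id]
        amplified = ntc.ct.dropna() < NTC_CT_FLOOR
        if amplified.any():
            raise RunInvalidError("NTC amplification detected")
        if len(self.calibrator_ids) != 3:
            raise ValueError("a run requires three calibrator samples")

    @classmethod
    def from_table(cls, df: pd.DataFrame, calibrator_ids: list[str],
                   ntc_id: str, control_target: str) -> "QpcrPlate":
        need = {"sample_id", "target_id", "replicate", "ct"}
        if not need.issubset(df.columns):
            raise ValueError(f"plate table needs columns {sorted(need)}")
        return cls(df.copy(), list(calibrator_ids), ntc_id, control_target)


@dataclasses.dataclass
class RqResult:
    sample_id: str
    target_id: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    copy_call: int | str | None = None    # 0..4 or 'equivocal'
    needs_retest: bool = False
    flags: list[str] = dataclasses.field(default_factory=list)


def _summarize_replicates(cts: pd.Series, outlier_ct: float = 0.5
                          ) -> tuple[float | None, list[str]]:
    """Mean Ct after triplicate hygiene: a replicate further than
    ``outlier_ct`` cycles from the median of three is dropped; with fewer
    than two usable replicates the result is flagged for retest."""
    vals = cts.dropna().to_numpy()
    flags = []
    if len(vals) < 3:
        flags.append("missing_replicate")
    if len(vals) == 0:
        return None, flags + ["no_amplification"]
    med = float(np.median(vals))
    kept = vals[np.abs(vals - med) <= outlier_ct]
    if len(kept) < len(vals):
        flags.append("replicate_outlier_dropped")
    if len(kept) < 2:
        return None, flags + ["insufficient_replicates"]
    return float(kept.mean()), flags


def compute_rq(plate: QpcrPlate, *, outlier_ct: float = 0.5) -> list[RqResult]:
    """Relative quantity per (sample, target): 2^-(dCt - median calibrator
    dCt). Calibrators are included in the output (their RQ self-tests near
    1); the NTC is excluded."""
    plate.validate()
    w = plate.wells
    targets = [t for t in w.target_id.unique() if t != plate.control_target]
    samples = [s for s in w.sample_id.unique() if s != plate.ntc_id]

    mean_ct: dict[tuple[str, str], tuple[float | None, list[str]]] = {}
    for (sid, tid), grp in w.groupby(["sample_id", "target_id"]):
        mean_ct[(sid, tid)] = _summarize_replicates(grp.ct, outlier_ct)

    def dct(sid: str, tid: str) -> tuple[float | None, list[str]]:
        t, tf = mean_ct.get((sid, tid), (None, ["no_wells"]))
        c, cf = mean_ct.get((sid, plate.control_target), (None, ["no_wells"]))
        if t is None or c is None:
            return None, tf + cf
        return t - c, tf + cf

    results: list[RqResult] = []
    for tid in targets:
        cal_dcts = [d for d, _f in (dct(c, tid) for c in plate.calibrator_ids)
                    if d is not None]
        if not cal_dcts:
            raise RunInvalidError(f"no usable calibrator dCt for target {tid}")
        cal_med = float(np.median(cal_dcts))
        for sid in samples:
            d, flags = dct(sid, tid)
            if d is None:
                results.append(RqResult(sid, tid, np.nan, np.nan, np.nan,
                                        copy_call="equivocal",
                                        needs_retest=True, flags=flags))
                continue
            ddct = d - cal_med
            results.append(RqResult(sid, tid, d, ddct, float(2.0 ** -ddct),
                                    flags=flags))
    return results


# ---------------------------------------------------------------------------
# copy-number assignment
# ---------------------------------------------------------------------------

#: Default conservative RQ ranges; gaps between ranges are equivocal.
DEFAULT_RQ_RANGES: dict[int, tuple[float, float]] = {
    0: (0.0, 0.2),       # upper bound exclusive
    1: (0.35, 0.65),
    2: (0.8, 1.2),
    3: (1.3, 1.7),
}


def _validate_ranges(ranges: dict[int, tuple[float, float]]) -> None:
    items = sorted(ranges.items(), key=lambda kv: kv[1][0])
    prev_hi = -np.inf
    for copies, (lo, hi) in items:
        if lo >= hi:
            raise ValueError(f"empty RQ range for {copies} copies")
        if lo < prev_hi:
            raise ValueError("overlapping RQ ranges")
        prev_hi = hi


def assign_copy_number(
    rq: float,
    ranges: dict[int, tuple[float, float]] | None = None,
) -> int | str:
    """Map an RQ to a copy number; values between ranges are 'equivocal'
    (requiring repeat testing)."""
    if ranges is None:
        ranges = DEFAULT_RQ_RANGES
    _validate_ranges(ranges)
    if not np.isfinite(rq):
        return "equivocal"
    for copies, (lo, hi) in ranges.items():
        if copies == 0 and rq < hi:
            return 0
        if lo <= rq <= hi:
            return copies
    return "equivocal"


def call_copy_numbers(results: list[RqResult],
                      ranges: dict[int, tuple[float, float]] | None = None
                      ) -> list[RqResult]:
    for r in results:
        if r.copy_call is None:
            r.copy_call = assign_copy_number(r.rq, ranges)
            if r.copy_call == "equivocal":
                r.needs_retest = True
    return results


# ---------------------------------------------------------------------------
# reconciliation with NGS del/dup calls
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReconcileResult:
    validated: list[DelDupCall]
    dropped_fp: list[DelDupCall]
    pending_retest: list[DelDupCall]
    unconfirmable: list[DelDupCall]


def exon_target_id(exon_number: int) -> str:
    return f"E{exon_number:02d}"


def reconcile(
    deldup_calls: list[DelDupCall],
    rq_results: list[RqResult],
    *,
    sample_id: str | None = None,
) -> ReconcileResult:
    """Validate NGS del/dup calls against exon qPCR copy calls.

    A call validates iff every tested exon in its span has a copy call
    consistent with the event type (deletion: 0 or 1 copies; duplication: 3
    or 4). Any inconsistent exon drops the call as a false positive; an
    equivocal exon without an inconsistency leaves the call pending retest;
    a call with no qPCR coverage in its span is unconfirmable.
    """
    by_target: dict[str, RqResult] = {}
    for r in rq_results:
        if sample_id is None or r.sample_id == sample_id:
            by_target[r.target_id] = r

    out = ReconcileResult([], [], [], [])
    for call in deldup_calls:
        tested = [by_target[exon_target_id(x)]
                  for x in range(call.exon_first, call.exon_last + 1)
                  if exon_target_id(x) in by_target]
        if not tested:
            out.unconfirmable.append(call)
            continue
        ok = {0, 1} if call.type == "del" else {3, 4}
        consistent = [t for t in tested if t.copy_call in ok]
        equivocal = [t for t in tested if t.copy_call == "equivocal"]
        inconsistent = [t for t in tested
                        if t.copy_call not in ok and t.copy_call != "equivocal"]
        if inconsistent:
            out.dropped_fp.append(call)
        elif equivocal:
            out.pending_retest.append(call)
        else:
            assert len(consistent) == len(tested)
            out.validated.append(dataclasses.replace(call, validated=True))
    return out
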