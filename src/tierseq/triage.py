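"""First-tier IRT gating and the per-infant screening algorithm.

Routing: infants in the daily top 5% of IRT reflex to second-tier panel
genotyping; those with ultra-high IRT (VHIRT, top 0.1% over a trailing
10-day window) and no panel variants additionally receive full third-tier
analysis. Outcomes: two or more distinct actionable, confirmed variants →
screen-positive referral; exactly one → carrier letter (genetic counseling
recommendation); none → screen negative, recorded as VHIRT-negative when the
infant cleared full third-tier analysis on the VHIRT route.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import pandas as pd

from .deldup import DelDupCall
from .polytgt import RepeatDiplotypeResult
from .variants import Variant

ACTIONABLE = {"CF-causing", "P", "LP", "VCC", "VOUS"}
NOT_ACTIONABLE = {"LB", "B", "non-CF-causing"}


class UnknownClassificationError(ValueError):
    """An unrecognized classification label; forces curation, never silent."""


def actionable(classification: str) -> bool:
    if classification in ACTIONABLE:
        return True
    if classification in NOT_ACTIONABLE:
        return False
    raise UnknownClassificationError(classification)


# ---------------------------------------------------------------------------
# IRT gate
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank percentile on the empirical distribution (tie-stable)."""
    s = sorted(values)
    if not s:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q / 100.0 * len(s)))
    return float(s[rank - 1])


@dataclasses.dataclass
class IrtGateResult:
    flagged: set[str]                 # daily top 5% -> second tier
    vhirt: set[str]                   # top 0.1% over the trailing window
    daily_cutoffs: dict[str, float]
    vhirt_cutoffs: dict[str, float]


def irt_gate(
    records: pd.DataFrame,
    *,
    daily_top_pct: float = 5.0,
    vhirt_top_pct: float = 0.1,
    window_days: int = 10,
) -> IrtGateResult:
    """Flag the daily top ``daily_top_pct``% (ties at the cutoff included)
    and the VHIRT set over the trailing ``window_days``-day window.

    ``records`` needs columns infant_id, collection_date, irt_ng_ml.
    """
    df = records.copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    days = sorted(df["collection_date"].unique())
    flagged: set[str] = set()
    vhirt: set[str] = set()
    daily_cut: dict[str, float] = {}
    vhirt_cut: dict[str, float] = {}
    for d in days:
        day = df[df["collection_date"] == d]
        if day.empty:
            warnings.warn(f"no IRT records on {d}; day skipped")
            continue
        cut = nearest_rank_percentile(day["irt_ng_ml"], 100.0 - daily_top_pct)
        key = pd.Timestamp(d).date().isoformat()
        daily_cut[key] = cut
        flagged.update(day.loc[day["irt_ng_ml"] >= cut, "infant_id"])
        lo = pd.Timestamp(d) - pd.Timedelta(days=window_days - 1)
        win = df[(df["collection_date"] >= lo) & (df["collection_date"] <= d)]
        vcut = nearest_rank_percentile(win["irt_ng_ml"], 100.0 - vhirt_top_pct)
        vhirt_cut[key] = vcut
        vhirt.update(day.loc[day["irt_ng_ml"] >= vcut, "infant_id"])
    return IrtGateResult(flagged=flagged, vhirt=vhirt,
                         daily_cutoffs=daily_cut, vhirt_cutoffs=vhirt_cut)


# ---------------------------------------------------------------------------
# per-infant screening
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReportableVariant:
    variant: Variant | DelDupCall
    classification: str
    confirmed: bool
    label: str = ""


@dataclasses.dataclass
class Tier3Bundle:
    reportable: list[ReportableVariant]
    polytgt: RepeatDiplotypeResult | None = None


@dataclasses.dataclass
class ScreenConfig:
    count_5t_with_r117h: bool = True
    r117h_labels: tuple[str, ...] = ("R117H",)


@dataclasses.dataclass
class ScreenResult:
    infant_id: str
    tier_reached: str                 # 'IRT-only', 'tier2', 'tier3'
    reportable_variants: list[ReportableVariant]
    polytgt: RepeatDiplotypeResult | None
    outcome: str                      # negative / VHIRT-negative / carrier-letter / referral
    rationale: str


class PendingConfirmationError(RuntimeError):
    """An actionable variant lacks orthogonal confirmation; the report is
    withheld until the confirmation result is in."""


def screen_infant(
    infant_id: str,
    *,
    irt_flagged: bool,
    vhirt: bool,
    tier2_reportable: list[ReportableVariant] | None = None,
    tier3: Tier3Bundle | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Apply the screening algorithm to one infant.

    Distinct actionable confirmed variants across tiers are counted; two
    variants are counted as two even if potentially in cis (phase is unknown
    at screening — referral resolves it). When R117H is present the polyTG/T
    result is attached, and a 5T allele counts toward the total when
    configured (default).
    """
    if not irt_flagged:
        return ScreenResult(infant_id, "IRT-only", [], None, "negative",
                            "IRT below daily top-5% cutoff")
    rules = [f"IRT in daily top 5%{' and VHIRT' if vhirt else ''}"]
    tier_reached = "tier2"
    variants: dict[str, ReportableVariant] = {}
    for rv in (tier2_reportable or []):
        if actionable(rv.classification):
            variants[str(rv.variant) + rv.label] = rv
    polytgt = None
    if tier3 is not None:
        tier_reached = "tier3"
        for rv in tier3.reportable:
            if actionable(rv.classification):
                variants[str(rv.variant) + rv.label] = rv
        polytgt = tier3.polytgt

    unconfirmed = [rv for rv in variants.values() if not rv.confirmed]
    if unconfirmed:
        raise PendingConfirmationError(
            f"{infant_id}: unconfirmed reportable variant(s): "
            + ", ".join(rv.label or str(rv.variant) for rv in unconfirmed)
        )

    reportable = list(variants.values())
    n = len(reportable)
    has_r117h = any(rv.label in config.r117h_labels for rv in reportable)
    if has_r117h and polytgt is not None and polytgt.diplotype is not None:
        rules.append("R117H present: polyTG/T diplotype attached")
        has_5t = any(h.t_len == 5 for h in polytgt.diplotype)
        if has_5t and config.count_5t_with_r117h:
            n += 1
            rules.append("5T allele counted with R117H")

    if n >= 2:
        outcome = "referral"
        rules.append(f"{n} actionable variants -> screen positive referral")
    elif n == 1:
        outcome = "carrier-letter"
        rules.append("one actionable variant -> carrier letter")
    elif vhirt and tier3 is not None:
        outcome = "VHIRT-negative"
        rules.append("VHIRT with no variants after full third-tier analysis")
    else:
        outcome = "negative"
        rules.append("no actionable variants")
    return ScreenResult(infant_id, tier_reached, reportable, polytgt, outcome,
                        "; ".join(rules))


def summarize_outcomes(results: list[ScreenResult]) -> pd.DataFrame:
    """Cohort summary with one row per outcome class."""
    order = ["negative", "VHIRT-negative", "carrier-letter", "referral"]
    counts = {o: 0 for o in order}
    for r in results:
        counts[r.outcome] += 1
    return pd.DataFrame({"outcome": order, "n": [counts[o] for o in order]})
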