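import numpy as np
import pytest

from tierseq.polytgt import RepeatHaplotype, RepeatDiplotypeResult
from tierseq.simulate import simulate_irt_population
from tierseq.triage import (PendingConfirmationError, ReportableVariant,
                            ScreenConfig, Tier3Bundle,
                            UnknownClassificationError, actionable, irt_gate,
                            nearest_rank_percentile, screen_infant,
                            summarize_outcomes)
from tierseq.variants import Variant


# ---------------------------------------------------------------------------
# IRT gate
# ---------------------------------------------------------------------------

def test_daily_flag_rate_near_five_percent():
    df = simulate_irt_population(10, 200, seed=2)
    gate = irt_gate(df)
    per_day = len(gate.flagged) / 10
    assert 9 <= per_day <= 12   # 5% of 200, ties included at the cutoff


def test_daily_cutoff_on_calibrated_population():
    df = simulate_irt_population(10, 2000, seed=4)
    gate = irt_gate(df)
    cuts = list(gate.daily_cutoffs.values())
    assert 45 <= float(np.median(cuts)) <= 61   # ~53 ng/mL scale


def test_vhirt_rarer_than_daily_flag():
    df = simulate_irt_population(10, 2000, seed=4)
    gate = irt_gate(df)
    assert gate.vhirt <= gate.flagged
    assert len(gate.vhirt) <= 0.005 * len(df)


def test_extreme_value_always_flagged():
    df = simulate_irt_population(1, 50, seed=1)
    df.loc[0, "irt_ng_ml"] = 1e4
    gate = irt_gate(df)
    assert df.loc[0, "infant_id"] in gate.flagged
    assert df.loc[0, "infant_id"] in gate.vhirt


def test_nearest_rank_is_an_observed_value():
    vals = [3.0, 1.0, 2.0, 10.0]
    assert nearest_rank_percentile(vals, 95) in vals
    with pytest.raises(ValueError):
        nearest_rank_percentile([], 95)


# ---------------------------------------------------------------------------
# actionability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cls,expect", [
    ("CF-causing", True), ("P", True), ("LP", True), ("VCC", True),
    ("VOUS", True), ("LB", False), ("B", False), ("non-CF-causing", False),
])
def test_actionable_vocabulary(cls, expect):
    assert actionable(cls) is expect


def test_unknown_classification_forces_curation():
    with pytest.raises(UnknownClassificationError):
        actionable("probably fine")


# ---------------------------------------------------------------------------
# screening outcomes
# ---------------------------------------------------------------------------

def rv(label, cls="CF-causing", confirmed=True, pos=100):
    return ReportableVariant(Variant(pos, "A", "T"), cls, confirmed, label)


def poly_result(t1=7, tg1=11, t2=7, tg2=11):
    a = RepeatHaplotype(t_len=t1, tg_len=tg1)
    b = RepeatHaplotype(t_len=t2, tg_len=tg2)
    pair = tuple(sorted((a, b)))
    return RepeatDiplotypeResult({a: 100, b: 100}, 200, pair, "called")


def test_two_variants_refer():
    res = screen_infant("I1", irt_flagged=True, vhirt=False,
                        tier2_reportable=[rv("F508del", pos=100),
                                          rv("W1282X", pos=200)])
    assert res.outcome == "referral"


def test_one_variant_carrier_letter():
    res = screen_infant("I2", irt_flagged=True, vhirt=False,
                        tier2_reportable=[rv("F508del")])
    assert res.outcome == "carrier-letter"


def test_vhirt_clean_after_tier3_is_negative():
    res = screen_infant("I3", irt_flagged=True, vhirt=True,
                        tier2_reportable=[],
                        tier3=Tier3Bundle(reportable=[], polytgt=poly_result()))
    assert res.outcome == "VHIRT-negative"
    assert res.tier_reached == "tier3"


def test_unflagged_infant_is_negative_at_irt():
    res = screen_infant("I4", irt_flagged=False, vhirt=False)
    assert res.outcome == "negative"
    assert res.tier_reached == "IRT-only"


def test_benign_variants_do_not_count():
    res = screen_infant("I5", irt_flagged=True, vhirt=False,
                        tier2_reportable=[rv("T854T", cls="B")])
    assert res.outcome == "negative"


def test_unconfirmed_variant_withholds_result():
    with pytest.raises(PendingConfirmationError):
        screen_infant("I6", irt_flagged=True, vhirt=False,
                      tier2_reportable=[rv("F508del", confirmed=False)])


def test_r117h_with_5t_counts_toward_referral():
    bundle = Tier3Bundle(reportable=[], polytgt=poly_result(t1=5, tg1=12))
    res = screen_infant("I7", irt_flagged=True, vhirt=False,
                        tier2_reportable=[rv("R117H", cls="VCC")],
                        tier3=bundle)
    assert res.outcome == "referral"
    off = ScreenConfig(count_5t_with_r117h=False)
    res = screen_infant("I7", irt_flagged=True, vhirt=False,
                        tier2_reportable=[rv("R117H", cls="VCC")],
                        tier3=bundle, config=off)
    assert res.outcome == "carrier-letter"


def test_added_variant_never_softens_outcome():
    severity = {"negative": 0, "VHIRT-negative": 0, "carrier-letter": 1,
                "referral": 2}
    variants = [rv("A", pos=100), rv("B", pos=200), rv("C", pos=300)]
    prev = -1
    for k in range(4):
        res = screen_infant("I8", irt_flagged=True, vhirt=False,
                            tier2_reportable=variants[:k])
        assert severity[res.outcome] >= prev
        prev = severity[res.outcome]


def test_cohort_outcomes_recover_truth():
    """50 infants with constructed genotypes map to exactly the outcomes
    their variant counts imply, one outcome each."""
    rng = np.random.default_rng(12)
    results = []
    expected = []
    for i in range(50):
        n_var = int(rng.integers(0, 3))
        flagged = bool(rng.random() < 0.5) or n_var > 0
        vhirt = flagged and rng.random() < 0.2
        variants = [rv(f"V{i}.{j}", pos=100 + 10 * j) for j in range(n_var)]
        tier3 = None
        if vhirt and not variants:
            tier3 = Tier3Bundle(reportable=[], polytgt=poly_result())
        res = screen_infant(f"N{i}", irt_flagged=flagged, vhirt=vhirt,
                            tier2_reportable=variants, tier3=tier3)
        results.append(res)
        if not flagged:
            expected.append("negative")
        elif n_var >= 2:
            expected.append("referral")
        elif n_var == 1:
            expected.append("carrier-letter")
        elif vhirt:
            expected.append("VHIRT-negative")
        else:
            expected.append("negative")
    assert [r.outcome for r in results] == expected
    summary = summarize_outcomes(results)
    assert summary.n.sum() == 50
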