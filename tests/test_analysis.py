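"""Knockout panels, crosstalk-combination sweeps, restoration scoring and
gap-filling diagnostics."""

import pandas as pd
import pytest

from nutlogic import analysis
from nutlogic.engine import InputCondition
from nutlogic.errors import ConfigurationError, ModelConsistencyError
from nutlogic.yeast_model import (
    RGT2_SNF3_KO,
    SNF1_KO,
    TPK_BCY1_KO,
    WT,
    build_glucose_model,
)


@pytest.fixture(scope="module")
def rgt2snf3_sweep(glucose_wt):
    scenario = analysis.packaged_scenario(RGT2_SNF3_KO, glucose_wt)
    return scenario, analysis.crosstalk_sweep(scenario, glucose_wt)


# ---------------------------------------------------------------------------
# knockout panel


def test_knockout_panel_differing_groups(glucose_wt):
    panel = analysis.knockout_panel(definition=glucose_wt)
    by_key = {
        (row["perturbation"], row["condition"]): row["differs_from_wt"]
        for _, row in panel.iterrows()
    }
    assert by_key[(WT, "glucose=1")] == frozenset()
    assert by_key[(WT, "glucose=0")] == frozenset()
    assert by_key[(SNF1_KO, "glucose=0")] == frozenset({"SUC"})
    assert by_key[(SNF1_KO, "glucose=1")] == frozenset()
    assert by_key[(RGT2_SNF3_KO, "glucose=1")] == frozenset({"HXT", "HXK"})
    assert by_key[(TPK_BCY1_KO, "glucose=1")] == frozenset({"PDS"})
    # STRE stays wild-type in the PKA deletion (Xxx4 dephosphorylates Msn2/4)
    assert "STRE" not in by_key[(TPK_BCY1_KO, "glucose=1")]


# ---------------------------------------------------------------------------
# classification


def test_classify_pattern_three_way():
    wt = {"SUC": 0, "HXT": 1}
    base = {"SUC": 0, "HXT": 0}
    assert analysis.classify_pattern(dict(wt), wt, base) == analysis.WT_LIKE
    assert analysis.classify_pattern(dict(base), wt, base) == analysis.PERTURBED_LIKE
    assert analysis.classify_pattern({"SUC": 1, "HXT": 1}, wt, base) == analysis.OTHER
    # tie resolves to WT-like
    assert analysis.classify_pattern(dict(wt), wt, dict(wt)) == analysis.WT_LIKE
    with pytest.raises(ModelConsistencyError):
        analysis.classify_pattern({"SUC": 0}, wt, base)


# ---------------------------------------------------------------------------
# sweep


def test_sweep_completeness(rgt2snf3_sweep):
    _, sweep = rgt2snf3_sweep
    flag_cols = [f"ct{i}" for i in analysis.SWEEP_CROSSTALK_IDS]
    assert len(sweep) == 128
    assert not sweep[flag_cols].duplicated().any()
    for col in flag_cols:
        assert sweep[col].sum() == 64  # each reaction active in half the combos


def test_rgt2snf3_sweep_wt_like_rows_are_those_with_crosstalk_1_or_3(rgt2snf3_sweep):
    """Independent enumeration oracle: a row is restored iff crosstalk 1
    or 3 is active, giving 128 - 32 = 96 WT-like rows."""
    _, sweep = rgt2snf3_sweep
    predicted = (sweep["ct1"] == 1) | (sweep["ct3"] == 1)
    observed = sweep["classification"] == analysis.WT_LIKE
    assert (predicted == observed).all()
    assert observed.sum() == 96


def test_all_off_baseline_row_is_perturbed_like(rgt2snf3_sweep):
    _, sweep = rgt2snf3_sweep
    flag_cols = [f"ct{i}" for i in analysis.SWEEP_CROSSTALK_IDS]
    row = sweep[(sweep[flag_cols] == 0).all(axis=1)]
    assert list(row["classification"]) == [analysis.PERTURBED_LIKE]


def test_restoration_report_rgt2snf3(rgt2snf3_sweep):
    _, sweep = rgt2snf3_sweep
    score = analysis.restoration_report(sweep)
    assert score.restoring == frozenset({1, 3})
    for ct_id in (1, 3):
        assert score.n_active[ct_id] == 64
        assert score.fraction[ct_id] == 1.0
    for ct_id in (2, 4, 5, 6, 8):
        assert score.fraction[ct_id] < 1.0


@pytest.mark.parametrize("perturbation", [SNF1_KO, TPK_BCY1_KO])
def test_no_crosstalk_combination_rescues_snf1_or_pka_deletion(glucose_wt, perturbation):
    scenario = analysis.packaged_scenario(perturbation, glucose_wt)
    sweep = analysis.crosstalk_sweep(scenario, glucose_wt)
    assert (sweep["classification"] != analysis.WT_LIKE).all()
    assert analysis.restoration_report(sweep).restoring == frozenset()


def test_restoration_report_rejects_incomplete_sweep(rgt2snf3_sweep):
    _, sweep = rgt2snf3_sweep
    with pytest.raises(ConfigurationError):
        analysis.restoration_report(sweep.head(10))


def test_scenario_baseline_differs_from_wt(glucose_wt):
    for name in analysis.PACKAGED_SCENARIOS:
        scenario = analysis.packaged_scenario(name, glucose_wt)
        assert scenario.baseline != scenario.wt_reference


def test_unknown_scenario_rejected(glucose_wt):
    with pytest.raises(ConfigurationError):
        analysis.packaged_scenario("mig1Δ", glucose_wt)


# ---------------------------------------------------------------------------
# gap diagnostics


def test_without_gap_fillers_first_condition_ok_switch_fails(glucose_base):
    reports = analysis.gap_diagnostic(glucose_base)
    assert len(reports) == 2
    for step in reports:
        assert step.failing_groups_first == frozenset()
        assert step.failing_groups_after_switch  # non-empty in both directions
        assert step.frozen_components


def test_full_wt_model_switches_cleanly(glucose_wt):
    reports = analysis.gap_diagnostic(glucose_wt)
    for step in reports:
        assert step.failing_groups_first == frozenset()
        assert step.failing_groups_after_switch == frozenset()


def test_phosphatases_alone_do_not_close_the_gaps(glucose_gaps_only):
    """Xxx1-Xxx4 without crosstalks 7/9: at least one switch direction
    still fails (the two crosstalks are gaps five and six)."""
    reports = analysis.gap_diagnostic(glucose_gaps_only)
    assert any(step.failing_groups_after_switch for step in reports)
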