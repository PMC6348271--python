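"""Packaged model content: rosters, rule counts, wild-type behavior and
the component-level predictions validated experimentally."""

import pytest

from nutlogic.engine import InputCondition, SimulationConfig, configure_model, predict, run_protocol
from nutlogic.errors import ConfigurationError, ModelConsistencyError
from nutlogic.yeast_model import (
    EXPECTED_NCR,
    GeneExpressionPattern,
    PERTURBATION_KNOCKOUTS,
    RGT2_SNF3_KO,
    SNF1_KO,
    TPK_BCY1_KO,
    WT,
    build_full_model,
    build_glucose_model,
    build_wt_model,
    expected_pattern,
    gene_status,
    group_pattern,
    model_census,
)


# ---------------------------------------------------------------------------
# census


def test_glucose_reconstruction_census(glucose_base):
    census = model_census(glucose_base)
    assert census["components"] == 48
    assert census["proteins"] == 45
    assert census["metabolites"] == 3
    assert census["base_rules"] == 61
    assert census["complexes"] == 1
    assert census["unknown_components"] == 0


def test_gap_filling_adds_six_conditions_and_four_unknowns(glucose_base, glucose_gaps_only):
    census = model_census(glucose_gaps_only)
    assert census["unknown_components"] == 4
    assert census["components"] - model_census(glucose_base)["components"] == 4
    # six gap conditions: 4 phosphatase rules + the 2 WT-required crosstalks
    assert census["gap_conditions"] == 6
    assert census["gap_filler_rules"] == 4


def test_full_model_census(full_model):
    census = model_census(full_model)
    assert census["components"] == 67
    assert census["known_proteins"] == 57
    assert census["proteins"] == 63  # including the 6 unknowns
    assert census["metabolites"] == 4
    assert census["unknown_components"] == 6
    assert census["complexes"] == 2
    assert census["tor_rules"] == 10
    assert census["tor_pathway_proteins"] == 15
    assert census["crosstalk_entries"] == 13
    assert census["target_genes"] == 19


def test_each_component_in_exactly_one_table(full_model):
    from nutlogic.engine import default_state

    tables = default_state(full_model, InputCondition(1, 1)).tables()
    names = [c.name for table in tables.values() for c in table]
    assert len(names) == len(set(names)) == len(full_model.components)


# ---------------------------------------------------------------------------
# wild-type truth table


@pytest.mark.parametrize("glucose", [1, 0])
def test_wt_group_pattern_matches_expectation(glucose_wt, glucose):
    condition = InputCondition(glucose)
    got = group_pattern(predict(glucose_wt, condition))
    assert got == expected_pattern(condition, WT)


@pytest.mark.parametrize("glucose,nitrogen", [(1, 1), (1, 0), (0, 0), (0, 1)])
def test_full_model_ncr_readout(glucose, nitrogen):
    """NCR genes follow nitrogen, except that the Snf1-to-Gln3 crosstalk
    switches them on under glucose limitation even with nitrogen."""
    model = build_full_model(crosstalk_flags={7: 1, 9: 1, 13: 1})
    pattern = group_pattern(predict(model, InputCondition(glucose, nitrogen)))
    assert pattern["NCR"] == EXPECTED_NCR[(glucose, nitrogen)]


def test_ncr_induction_at_low_glucose_requires_the_crosstalk():
    model = build_wt_model("full")  # crosstalk 13 off
    assert group_pattern(predict(model, InputCondition(0, 1)))["NCR"] == 0


# ---------------------------------------------------------------------------
# component-level predictions (validated by microscopy / Western blot)


@pytest.mark.parametrize("glucose", [1, 0])
def test_transcription_factor_localization_and_snf1_phosphorylation(glucose_wt, glucose):
    lss = predict(glucose_wt, InputCondition(glucose))
    assert (lss["Msn2"].localization == "nucleus") == (glucose == 0)
    assert (lss["Mig1"].localization == "nucleus") == (glucose == 1)
    assert lss["Rgt1"].localization == "nucleus"  # both conditions
    assert lss["Ssn6"].localization == "nucleus"
    assert lss["Tup1"].localization == "nucleus"
    assert lss["Snf1"].phosphorylation == (1 if glucose == 0 else 0)


# ---------------------------------------------------------------------------
# switching


def test_repeated_switching_is_reversible(glucose_wt):
    seq = tuple(InputCondition(g) for g in (1, 0, 1))
    results = run_protocol(glucose_wt, SimulationConfig(condition_sequence=seq))
    assert results[0][1] == results[2][1]
    short = run_protocol(
        glucose_wt, SimulationConfig(condition_sequence=(InputCondition(0), InputCondition(1)))
    )
    assert results[2][1] == short[-1][1]


# ---------------------------------------------------------------------------
# gene readout


def test_gene_groups_share_status_within_group(glucose_wt):
    pattern = gene_status(predict(glucose_wt, InputCondition(1)))
    groups = pattern.groups()
    assert set(groups) == {"SUC", "HXT", "HXK", "STRE", "PDS"}
    for gene, status in pattern.genes.items():
        assert status == groups[pattern.group_of[gene]]


def test_disagreeing_group_members_raise():
    pattern = GeneExpressionPattern({"HXT1": 1, "HXT2": 0}, {"HXT1": "HXT", "HXT2": "HXT"})
    with pytest.raises(ModelConsistencyError):
        pattern.groups()


# ---------------------------------------------------------------------------
# expected-pattern oracle table


def test_expected_pattern_deviations():
    g0, g1 = InputCondition(0), InputCondition(1)
    assert expected_pattern(g0, SNF1_KO) != expected_pattern(g0, WT)
    diff = {
        g
        for g in expected_pattern(g0, WT)
        if expected_pattern(g0, SNF1_KO)[g] != expected_pattern(g0, WT)[g]
    }
    assert diff == {"SUC"}
    diff = {
        g
        for g in expected_pattern(g1, WT)
        if expected_pattern(g1, RGT2_SNF3_KO)[g] != expected_pattern(g1, WT)[g]
    }
    assert diff == {"HXT", "HXK"}
    diff = {
        g
        for g in expected_pattern(g1, WT)
        if expected_pattern(g1, TPK_BCY1_KO)[g] != expected_pattern(g1, WT)[g]
    }
    assert diff == {"PDS"}
    with pytest.raises(ConfigurationError):
        expected_pattern(g1, "notAknockout")


def test_knockout_inertness_at_lss(glucose_wt):
    configured = configure_model(
        glucose_wt,
        knockouts=PERTURBATION_KNOCKOUTS[TPK_BCY1_KO],
        crosstalk_flags=glucose_wt.crosstalk_flags,
    )
    lss = predict(configured, InputCondition(1))
    for name in PERTURBATION_KNOCKOUTS[TPK_BCY1_KO]:
        comp = lss[name]
        assert comp.presence == 0
        assert comp.phosphorylation == 0 and comp.nucleotide == 0 and comp.dna_bound == 0
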