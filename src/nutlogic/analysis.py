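"""Perturbation experiments on the packaged model.

Three in-silico deletion scenarios alter the wild-type gene-expression
pattern: rgt2Δsnf3Δ in glucose (HXT/HXK groups), tpk1Δtpk2Δtpk3Δbcy1Δ in
glucose (PDS group) and snf1Δ without glucose (SUC group).  For each, all
2^7 = 128 on/off combinations of the sweepable crosstalk reactions
{1,2,3,4,5,6,8} are simulated (reactions 7 and 9 are wild-type
requirements and stay on), and each combination is scored as WT-like,
perturbed-like or other.  A crosstalk reaction "restores" a scenario if
the pattern is WT-like in every combination in which it is active.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .engine import InputCondition, ModelDefinition, configure_model, predict
from .errors import ConfigurationError, ModelConsistencyError
from .yeast_model import (
    PERTURBATION_KNOCKOUTS,
    RGT2_SNF3_KO,
    SNF1_KO,
    TPK_BCY1_KO,
    WT,
    WT_CROSSTALK_FLAGS,
    build_glucose_model,
    build_wt_model,
    expected_pattern,
    group_pattern,
)

SWEEP_CROSSTALK_IDS = (1, 2, 3, 4, 5, 6, 8)

WT_LIKE = "WT-like"
PERTURBED_LIKE = "perturbed-like"
OTHER = "other"


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class PerturbationScenario:
    """A knockout plus the nutrient condition whose expression pattern the
    knockout disturbs, with the WT reference and the all-crosstalk-off
    baseline pattern."""

    name: str
    knockouts: frozenset
    condition: InputCondition
    wt_reference: Mapping[str, int]
    baseline: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "wt_reference", dict(self.wt_reference))
        object.__setattr__(self, "baseline", dict(self.baseline))


def packaged_scenario(perturbation: str, definition: Optional[ModelDefinition] = None) -> PerturbationScenario:
    """Build one of the three packaged sweep scenarios.

    The baseline is simulated with the sweepable crosstalks off (only the
    WT-required reactions 7 and 9 active)."""
    conditions = {
        RGT2_SNF3_KO: InputCondition(glucose=1),
        TPK_BCY1_KO: InputCondition(glucose=1),
        SNF1_KO: InputCondition(glucose=0),
    }
    if perturbation not in conditions:
        raise ConfigurationError(
            f"no packaged sweep scenario for {perturbation!r}; expected one of "
            f"{sorted(conditions)}"
        )
    definition = definition if definition is not None else build_wt_model("glucose")
    condition = conditions[perturbation]
    knockouts = PERTURBATION_KNOCKOUTS[perturbation]
    wt_ref = group_pattern(predict(definition, condition))
    baseline_def = configure_model(definition, knockouts=knockouts, crosstalk_flags=definition.crosstalk_flags)
    baseline = group_pattern(predict(baseline_def, condition))
    return PerturbationScenario(perturbation, knockouts, condition, wt_ref, baseline)


PACKAGED_SCENARIOS = (RGT2_SNF3_KO, TPK_BCY1_KO, SNF1_KO)


# ---------------------------------------------------------------------------
# knockout panel


def knockout_panel(
    perturbations: Sequence[str] = (WT, SNF1_KO, RGT2_SNF3_KO, TPK_BCY1_KO),
    conditions: Sequence[InputCondition] = (InputCondition(1), InputCondition(0)),
    definition: Optional[ModelDefinition] = None,
) -> pd.DataFrame:
    """Predicted gene-group patterns for each (perturbation, condition).

    Every prediction pre-equilibrates at the opposite condition.  The
    ``differs_from_wt`` column holds the set of groups whose status
    deviates from the WT prediction at the same condition.
    """
    definition = definition if definition is not None else build_wt_model("glucose")
    wt_patterns = {c: group_pattern(predict(definition, c)) for c in conditions}
    rows = []
    for perturbation in perturbations:
        knockouts = PERTURBATION_KNOCKOUTS[perturbation]
        configured = configure_model(definition, knockouts=knockouts, crosstalk_flags=definition.crosstalk_flags)
        for condition in conditions:
            pattern = group_pattern(predict(configured, condition))
            wt_ref = wt_patterns[condition]
            differing = frozenset(g for g, v in pattern.items() if v != wt_ref[g])
            rows.append(
                {
                    "perturbation": perturbation,
                    "condition": condition.label(),
                    **pattern,
                    "differs_from_wt": differing,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pattern classification


def classify_pattern(
    pattern: Mapping[str, int],
    wt_ref: Mapping[str, int],
    baseline: Mapping[str, int],
) -> str:
    """WT-like if equal to the WT reference on all groups; otherwise
    perturbed-like if equal to the all-off baseline; otherwise other.
    Ties (wt_ref == baseline) resolve to WT-like."""
    if set(pattern) != set(wt_ref) or set(pattern) != set(baseline):
        raise ModelConsistencyError("patterns are defined over different group sets")
    if all(pattern[g] == wt_ref[g] for g in pattern):
        return WT_LIKE
    if all(pattern[g] == baseline[g] for g in pattern):
        return PERTURBED_LIKE
    return OTHER


# ---------------------------------------------------------------------------
# crosstalk sweep


def crosstalk_sweep(
    scenario: PerturbationScenario,
    definition: Optional[ModelDefinition] = None,
    sweep_ids: Sequence[int] = SWEEP_CROSSTALK_IDS,
) -> pd.DataFrame:
    """Simulate every on/off combination of the sweepable crosstalks.

    Each row is simulated independently with the WT-required crosstalks
    {7, 9} on plus the row's flag vector; the resulting group pattern is
    classified against the scenario's WT reference and baseline.
    """
    definition = definition if definition is not None else build_wt_model("glucose")
    rows = []
    for flags in itertools.product((0, 1), repeat=len(sweep_ids)):
        flag_map = dict(zip(sweep_ids, flags))
        configured = configure_model(
            definition,
            knockouts=scenario.knockouts,
            crosstalk_flags={**WT_CROSSTALK_FLAGS, **flag_map},
        )
        pattern = group_pattern(predict(configured, scenario.condition))
        row = {f"ct{i}": f for i, f in flag_map.items()}
        row.update(pattern)
        row["classification"] = classify_pattern(pattern, scenario.wt_reference, scenario.baseline)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# restoration scoring


@dataclass(frozen=True)
class RestorationScore:
    """Per-crosstalk restoration statistics over a complete sweep."""

    n_active: Mapping[int, int]
    n_wt_like_when_active: Mapping[int, int]
    fraction: Mapping[int, float]
    restoring: frozenset

    def __post_init__(self):
        object.__setattr__(self, "n_active", dict(self.n_active))
        object.__setattr__(self, "n_wt_like_when_active", dict(self.n_wt_like_when_active))
        object.__setattr__(self, "fraction", dict(self.fraction))
        object.__setattr__(self, "restoring", frozenset(self.restoring))


def restoration_report(
    sweep: pd.DataFrame,
    sweep_ids: Sequence[int] = SWEEP_CROSSTALK_IDS,
) -> RestorationScore:
    """Score each crosstalk reaction over a complete sweep table.

    The restoring set contains the reactions that yield a WT-like pattern
    in *every* combination in which they are active (fraction 1.0).
    """
    expected_rows = 2 ** len(sweep_ids)
    if len(sweep) != expected_rows:
        raise ConfigurationError(
            f"incomplete sweep: expected {expected_rows} rows, got {len(sweep)}"
        )
    n_active = {}
    n_wt = {}
    fraction = {}
    for ct_id in sweep_ids:
        col = f"ct{ct_id}"
        active_rows = sweep[sweep[col] == 1]
        n_active[ct_id] = int(len(active_rows))
        n_wt[ct_id] = int((active_rows["classification"] == WT_LIKE).sum())
        fraction[ct_id] = n_wt[ct_id] / n_active[ct_id] if n_active[ct_id] else 0.0
    restoring = frozenset(i for i in sweep_ids if n_active[i] > 0 and fraction[i] == 1.0)
    return RestorationScore(n_active, n_wt, fraction, restoring)


# ---------------------------------------------------------------------------
# gap-filling diagnostics


@dataclass(frozen=True)
class GapDiagnosticStep:
    """Outcome of one switch direction: the groups that mismatch the
    expected pattern after the switch, and the components whose state did
    not reset relative to a fresh simulation of the same condition."""

    first_condition: InputCondition
    second_condition: InputCondition
    failing_groups_first: frozenset
    failing_groups_after_switch: frozenset
    frozen_components: tuple


def gap_diagnostic(definition: Optional[ModelDefinition] = None) -> list:
    """Run both switch directions and report what fails after the switch.

    With the gap fillers and crosstalks 7/9 absent, the model reproduces
    the expected pattern at the first condition but cannot switch; the
    frozen-component list identifies the states that failed to reset,
    which is how the missing (gap-filling) reactions were located.
    """
    from .engine import SimulationConfig, run_protocol

    if definition is None:
        definition = build_glucose_model(include_gap_fillers=False)
    reports = []
    for first, second in ((InputCondition(1), InputCondition(0)), (InputCondition(0), InputCondition(1))):
        cfg = SimulationConfig(condition_sequence=(first, second))
        (c1, lss1), (c2, lss2) = run_protocol(definition, cfg)
        pat1 = group_pattern(lss1)
        pat2 = group_pattern(lss2)
        exp1 = expected_pattern(first, WT)
        exp2 = expected_pattern(second, WT)
        fail1 = frozenset(g for g in pat1 if pat1[g] != exp1[g])
        fail2 = frozenset(g for g in pat2 if pat2[g] != exp2[g])
        # reference: a fresh first-step simulation of the second condition
        fresh = run_protocol(definition, SimulationConfig(condition_sequence=(second,)))[0][1]
        frozen = tuple(sorted(lss2.diff(fresh)))
        reports.append(GapDiagnosticStep(first, second, fail1, fail2, frozen))
    return reports
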