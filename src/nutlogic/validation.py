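"""Self-check: re-run the packaged behavioral oracles.

Used by the ``nutlogic validate`` CLI command.  Each check compares a
fresh simulation against the published expectation patterns; the return
value is a list of human-readable failure descriptions (empty when the
installation behaves as packaged).
"""

from __future__ import annotations

from .engine import InputCondition, configure_model, predict
from .yeast_model import (
    PERTURBATION_KNOCKOUTS,
    RGT2_SNF3_KO,
    SNF1_KO,
    TPK_BCY1_KO,
    WT,
    build_wt_model,
    expected_pattern,
    group_pattern,
)


def run_validation_suite() -> list:
    failures = []
    definition = build_wt_model("glucose")
    for perturbation in (WT, SNF1_KO, RGT2_SNF3_KO, TPK_BCY1_KO):
        configured = configure_model(
            definition,
            knockouts=PERTURBATION_KNOCKOUTS[perturbation],
            crosstalk_flags=definition.crosstalk_flags,
        )
        for glucose in (1, 0):
            condition = InputCondition(glucose)
            got = group_pattern(predict(configured, condition))
            want = expected_pattern(condition, perturbation)
            if got != want:
                failures.append(
                    f"{perturbation} at {condition.label()}: predicted {got}, expected {want}"
                )
    from .analysis import crosstalk_sweep, packaged_scenario, restoration_report

    expected_restoring = {RGT2_SNF3_KO: {1, 3}, TPK_BCY1_KO: set(), SNF1_KO: set()}
    for perturbation, want in expected_restoring.items():
        scenario = packaged_scenario(perturbation, definition)
        score = restoration_report(crosstalk_sweep(scenario, definition))
        if set(score.restoring) != want:
            failures.append(
                f"{perturbation} sweep: restoring set {sorted(score.restoring)}, expected {sorted(want)}"
            )
    return failures
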