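"""Model serialization, steady-state reports, schematic export and CLI.

The model document is a versioned YAML mapping with sections
``components``, ``rules``, ``crosstalk``, ``gene_map`` and ``inputs``.
Condition expressions are stored as explicit and/or/not/atom trees (no
string parsing at load time), enum values as human-readable labels, and
rule order is preserved, so documents round-trip losslessly and diff
cleanly.
"""

from __future__ import annotations

import json
import sys
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import click
import pandas as pd
import yaml

from . import engine
from .engine import (
    And,
    Atom,
    ComponentSpec,
    Condition,
    CrosstalkEntry,
    Effect,
    InputCondition,
    ModelDefinition,
    ModelState,
    Not,
    Or,
    Rule,
    SimulationConfig,
    configure_model,
    predict,
    run_protocol,
)
from .errors import ConfigurationError, ModelFormatError
from .yeast_model import (
    GeneSpec,
    GeneExpressionPattern,
    build_glucose_model,
    build_full_model,
    build_wt_model,
    gene_status,
)

DOCUMENT_VERSION = 1

STATE_COLUMNS = ("name", "presence", "localization", "phosphorylation", "nucleotide", "dna_bound")


# ---------------------------------------------------------------------------
# condition <-> document


def condition_to_doc(condition: Condition) -> dict:
    if isinstance(condition, Atom):
        return {
            "atom": {
                "component": condition.component,
                "field": condition.field,
                "op": condition.op,
                "value": condition.value,
            }
        }
    if isinstance(condition, And):
        return {"and": [condition_to_doc(c) for c in condition.children]}
    if isinstance(condition, Or):
        return {"or": [condition_to_doc(c) for c in condition.children]}
    if isinstance(condition, Not):
        return {"not": condition_to_doc(condition.child)}
    raise ModelFormatError(f"unserializable condition node {condition!r}")


def condition_from_doc(doc: Mapping, path: str = "condition") -> Condition:
    if not isinstance(doc, Mapping) or len(doc) != 1:
        raise ModelFormatError(f"{path}: expected a single-key mapping, got {doc!r}")
    key, value = next(iter(doc.items()))
    if key == "atom":
        missing = {"component", "field", "op", "value"} - set(value)
        if missing:
            raise ModelFormatError(f"{path}.atom: missing keys {sorted(missing)}")
        if value["op"] not in ("eq", "ne"):
            raise ModelFormatError(f"{path}.atom: bad op {value['op']!r}")
        return Atom(value["component"], value["field"], value["value"], value["op"])
    if key == "and":
        return And(*(condition_from_doc(c, f"{path}.and[{i}]") for i, c in enumerate(value)))
    if key == "or":
        return Or(*(condition_from_doc(c, f"{path}.or[{i}]") for i, c in enumerate(value)))
    if key == "not":
        return Not(condition_from_doc(value, f"{path}.not"))
    raise ModelFormatError(f"{path}: unknown node kind {key!r}")


# ---------------------------------------------------------------------------
# rules / components <-> document


def _rule_to_doc(rule: Rule) -> dict:
    doc = {
        "id": rule.id,
        "pathway": rule.pathway,
        "class": rule.rule_class,
        "condition": condition_to_doc(rule.condition),
        "effects": [
            {"component": e.component, "field": e.field, "value": e.value} for e in rule.effects
        ],
        "citation": rule.citation,
    }
    if rule.crosstalk_id is not None:
        doc["crosstalk_id"] = rule.crosstalk_id
    return doc


def _rule_from_doc(doc: Mapping, path: str) -> Rule:
    for key in ("id", "pathway", "class", "condition", "effects"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing key {key!r}")
    effects = []
    for i, e in enumerate(doc["effects"]):
        for key in ("component", "field", "value"):
            if key not in e:
                raise ModelFormatError(f"{path}.effects[{i}]: missing key {key!r}")
        effects.append(Effect(e["component"], e["field"], e["value"]))
    return Rule(
        id=doc["id"],
        pathway=doc["pathway"],
        condition=condition_from_doc(doc["condition"], f"{path}.condition"),
        effects=tuple(effects),
        rule_class=doc["class"],
        crosstalk_id=doc.get("crosstalk_id"),
        citation=doc.get("citation", ""),
    )


def model_to_document(definition: ModelDefinition) -> dict:
    """Serialize a model definition to a plain mapping (stable order)."""
    return {
        "format_version": DOCUMENT_VERSION,
        "name": definition.name,
        "pathways": list(definition.pathways),
        "inputs": dict(definition.inputs),
        "components": [
            {
                "name": c.name,
                "kind": c.kind,
                "pathway": c.pathway,
                "default_localization": c.default_localization,
                "is_unknown": c.is_unknown,
            }
            for c in definition.components
        ],
        "rules": [_rule_to_doc(r) for r in definition.rules],
        "crosstalk": [
            {
                "id": e.id,
                "components": list(e.components),
                "description": e.description,
                "citation": e.citation,
                "wt_required": e.wt_required,
                "sweepable": e.sweepable,
                "rules": [_rule_to_doc(r) for r in e.rules],
            }
            for _, e in sorted(definition.crosstalk.items())
        ],
        "gene_map": [
            {"name": g.name, "group": g.group, "condition": condition_to_doc(g.condition)}
            for g in definition.gene_map
        ],
        "knockouts": sorted(definition.knockouts),
        "crosstalk_flags": {int(k): int(v) for k, v in sorted(definition.crosstalk_flags.items())},
    }


def document_to_model(doc: Mapping) -> ModelDefinition:
    """Rebuild a model definition from a document; validates consistency."""
    if not isinstance(doc, Mapping):
        raise ModelFormatError("document root must be a mapping")
    for key in ("format_version", "name", "pathways", "components", "rules", "crosstalk"):
        if key not in doc:
            raise ModelFormatError(f"document: missing section {key!r}")
    if doc["format_version"] != DOCUMENT_VERSION:
        raise ModelFormatError(f"unsupported format_version {doc['format_version']!r}")
    components = []
    for i, c in enumerate(doc["components"]):
        for key in ("name", "kind", "pathway"):
            if key not in c:
                raise ModelFormatError(f"components[{i}]: missing key {key!r}")
        components.append(
            ComponentSpec(
                c["name"],
                c["kind"],
                c["pathway"],
                c.get("default_localization"),
                c.get("is_unknown", False),
            )
        )
    rules = tuple(_rule_from_doc(r, f"rules[{i}]") for i, r in enumerate(doc["rules"]))
    crosstalk = {}
    for i, e in enumerate(doc["crosstalk"]):
        for key in ("id", "components", "description", "rules"):
            if key not in e:
                raise ModelFormatError(f"crosstalk[{i}]: missing key {key!r}")
        crosstalk[e["id"]] = CrosstalkEntry(
            id=e["id"],
            components=tuple(e["components"]),
            description=e["description"],
            citation=e.get("citation", ""),
            wt_required=e.get("wt_required", False),
            sweepable=e.get("sweepable", True),
            rules=tuple(_rule_from_doc(r, f"crosstalk[{i}].rules[{j}]") for j, r in enumerate(e["rules"])),
        )
    gene_map = tuple(
        GeneSpec(g["name"], g["group"], condition_from_doc(g["condition"], f"gene_map[{i}]"))
        for i, g in enumerate(doc.get("gene_map", []))
    )
    definition = ModelDefinition(
        name=doc["name"],
        pathways=tuple(doc["pathways"]),
        components=tuple(components),
        rules=rules,
        crosstalk=crosstalk,
        gene_map=gene_map,
        inputs=dict(doc.get("inputs", {})),
        knockouts=frozenset(doc.get("knockouts", ())),
        crosstalk_flags={int(k): int(v) for k, v in doc.get("crosstalk_flags", {}).items()},
    )
    try:
        definition.validate()
    except ConfigurationError:
        raise
    except Exception as err:  # surface consistency problems as format errors
        raise ModelFormatError(str(err)) from err
    return definition


def save_model(definition: ModelDefinition, path) -> None:
    """Write a model document as YAML (deterministic key order)."""
    doc = model_to_document(definition)
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False, default_flow_style=False)


def load_model(path) -> ModelDefinition:
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    return document_to_model(doc)


def load_packaged_model(name: str = "glucose") -> ModelDefinition:
    """Load one of the shipped model documents ('glucose' or 'full')."""
    if name not in ("glucose", "full"):
        raise ConfigurationError(f"no packaged model named {name!r}")
    ref = resources.files("nutlogic") / "data" / f"{name}_model.yaml"
    with ref.open() as handle:
        return document_to_model(yaml.safe_load(handle))


# ---------------------------------------------------------------------------
# state tables


def state_tables(state: ModelState) -> dict:
    """One DataFrame per pathway table, full state vectors as rows."""
    out = {}
    for pathway, components in state.tables().items():
        rows = []
        for comp in components:
            if comp.kind == "complex":
                rows.append({"name": comp.name, "active": comp.active})
            elif comp.kind == "metabolite":
                rows.append(
                    {"name": comp.name, "presence": comp.presence, "localization": comp.localization}
                )
            else:
                rows.append({c: getattr(comp, c) for c in STATE_COLUMNS})
        out[pathway] = pd.DataFrame(rows)
    return out


def write_state_tables(state: ModelState, destination) -> list:
    """Write one tab-separated table per pathway; returns written paths."""
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    written = []
    for pathway, table in state_tables(state).items():
        path = destination / f"state_{pathway}.tsv"
        table.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def write_gene_report(
    patterns: Sequence[tuple],
    destination,
) -> Path:
    """Write the per-step gene status file.

    ``patterns`` is a sequence of (step label, GeneExpressionPattern);
    one row per gene per step, stable ordering.
    """
    if not patterns:
        raise ConfigurationError("gene report requires at least one pattern")
    rows = []
    for label, pattern in patterns:
        if not isinstance(pattern, GeneExpressionPattern):
            raise ConfigurationError("expected GeneExpressionPattern instances")
        for gene in pattern.genes:
            rows.append(
                {
                    "step": label,
                    "gene": gene,
                    "group": pattern.group_of[gene],
                    "status": pattern.genes[gene],
                }
            )
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(destination, sep="\t", index=False)
    return destination


# ---------------------------------------------------------------------------
# schematic export


_COMPARTMENT_BANDS = {
    # y ranges of the three compartments in the 400-unit-tall canvas
    "membrane": (20, 70),
    "cytosol": (90, 230),
    "nucleus": (250, 370),
}
_BOX_W, _BOX_H, _GAP = 84, 30, 10


def render_schematic(state: ModelState, pathway: str) -> str:
    """Minimal deterministic SVG diagram of one pathway table.

    Membrane band, cytosol and nucleus regions; one labeled box per
    component placed by localization; a filled dot for a phosphorylation
    or nucleotide mark; a stem down to the DNA line for DNA-bound
    factors; knocked-out (absent) components are greyed out.
    """
    tables = state.tables()
    if pathway not in tables:
        raise ConfigurationError(f"unknown pathway {pathway!r}")
    components = tables[pathway]
    width = 720
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="400" '
        f'font-family="sans-serif" font-size="11">',
        f'<rect x="0" y="0" width="{width}" height="400" fill="white"/>',
        f'<rect x="0" y="20" width="{width}" height="50" fill="none" stroke="black" stroke-width="3"/>',
        f'<rect x="0" y="90" width="{width}" height="140" fill="#e8f5e9"/>',
        f'<rect x="0" y="250" width="{width}" height="120" fill="#eeeeee"/>',
        f'<line x1="0" y1="360" x2="{width}" y2="360" stroke="black" stroke-width="2"/>',
        f'<text x="4" y="14">{pathway}</text>',
        '<text x="4" y="84">membrane</text>',
        '<text x="4" y="244">cytosol</text>',
        '<text x="4" y="384">nucleus (DNA line below)</text>',
    ]
    counters = {band: 0 for band in _COMPARTMENT_BANDS}
    per_row = (width - 100) // (_BOX_W + _GAP)
    for comp in components:
        loc = getattr(comp, "localization", "cytosol")
        if comp.kind == "complex":
            loc = "cytosol"
        if loc == "extracellular":
            loc = "membrane"
        band = _COMPARTMENT_BANDS.get(loc, _COMPARTMENT_BANDS["cytosol"])
        slot = counters[loc if loc in counters else "cytosol"]
        counters[loc if loc in counters else "cytosol"] += 1
        x = 96 + (slot % per_row) * (_BOX_W + _GAP)
        y = band[0] + 8 + (slot // per_row) * (_BOX_H + _GAP)
        absent = getattr(comp, "presence", 1) == 0 and comp.kind != "complex"
        fill = "#cccccc" if absent else "#ffffff"
        stroke = "#999999" if absent else "black"
        parts.append(
            f'<g id="{comp.name}"><rect x="{x}" y="{y}" width="{_BOX_W}" height="{_BOX_H}" '
            f'fill="{fill}" stroke="{stroke}"/>'
            f'<text x="{x + 6}" y="{y + 19}" fill="{stroke}">{comp.name}</text>'
        )
        if not absent:
            if getattr(comp, "phosphorylation", 0) == 1 or getattr(comp, "nucleotide", 0) == 1:
                parts.append(f'<circle cx="{x + _BOX_W - 8}" cy="{y + 8}" r="5" fill="black"/>')
            if getattr(comp, "dna_bound", 0) == 1:
                parts.append(
                    f'<line x1="{x + _BOX_W // 2}" y1="{y + _BOX_H}" x2="{x + _BOX_W // 2}" '
                    f'y2="360" stroke="black" stroke-dasharray="3,2"/>'
                )
            if getattr(comp, "active", 0) == 1:
                parts.append(f'<circle cx="{x + _BOX_W - 8}" cy="{y + 8}" r="5" fill="black"/>')
        parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts)


def write_schematics(state: ModelState, destination) -> list:
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    written = []
    for pathway in state.definition.pathways:
        path = destination / f"schematic_{pathway}.svg"
        path.write_text(render_schematic(state, pathway))
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# CLI


def _parse_bit_sequence(text: str, name: str) -> list:
    try:
        bits = [int(x) for x in text.split(",") if x != ""]
    except ValueError:
        raise click.UsageError(f"--{name} must be a comma-separated 0/1 list")
    if not bits or any(b not in (0, 1) for b in bits):
        raise click.UsageError(f"--{name} must be a comma-separated 0/1 list")
    return bits


def _build(model: str, gap_fillers: bool, flags: Mapping[int, int]) -> ModelDefinition:
    if model == "full":
        return build_full_model(crosstalk_flags=flags)
    return build_glucose_model(include_gap_fillers=gap_fillers, crosstalk_flags=flags)


@click.group()
def cli():
    """Rule-based Boolean logic simulation of yeast nutrient signaling."""


@cli.command()
@click.option("--model", type=click.Choice(["glucose", "full"]), default="glucose", show_default=True)
@click.option("--glucose-sequence", default="0,1", show_default=True, help="comma-separated glucose bits")
@click.option("--nitrogen-sequence", default=None, help="comma-separated nitrogen bits (full model)")
@click.option("--knockout", multiple=True, help="component to delete (repeatable)")
@click.option("--crosstalk", default="7,9", show_default=True, help="comma-separated crosstalk ids to switch on")
@click.option("--gap-fillers/--no-gap-fillers", default=True, show_default=True)
@click.option("--out", type=click.Path(file_okay=False), required=True)
def simulate(model, glucose_sequence, nitrogen_sequence, knockout, crosstalk, gap_fillers, out):
    """Run a condition-switching protocol and write state/gene reports."""
    glucose_bits = _parse_bit_sequence(glucose_sequence, "glucose-sequence")
    if model == "full":
        nitrogen_bits = (
            _parse_bit_sequence(nitrogen_sequence, "nitrogen-sequence")
            if nitrogen_sequence
            else [1] * len(glucose_bits)
        )
        if len(nitrogen_bits) != len(glucose_bits):
            raise click.UsageError("glucose and nitrogen sequences must have equal length")
        sequence = tuple(InputCondition(g, n) for g, n in zip(glucose_bits, nitrogen_bits))
    else:
        sequence = tuple(InputCondition(g) for g in glucose_bits)
    try:
        flag_ids = [int(x) for x in crosstalk.split(",") if x != ""] if crosstalk else []
    except ValueError:
        raise click.UsageError("--crosstalk must be a comma-separated id list")
    definition = _build(model, gap_fillers, {i: 1 for i in flag_ids})
    try:
        definition = configure_model(definition, knockouts=set(knockout), crosstalk_flags=definition.crosstalk_flags)
        results = run_protocol(definition, SimulationConfig(condition_sequence=sequence))
    except ConfigurationError as err:
        raise click.ClickException(json.dumps({"error": str(err)}))
    out = Path(out)
    patterns = []
    for step, (condition, lss) in enumerate(results, start=1):
        step_dir = out / f"step{step}_{condition.label().replace(', ', '_').replace('=', '')}"
        write_state_tables(lss, step_dir)
        write_schematics(lss, step_dir)
        patterns.append((f"step{step} ({condition.label()})", gene_status(lss)))
    write_gene_report(patterns, out / "genes.tsv")
    config_echo = {
        "model": model,
        "conditions": [c.label() for c, _ in results],
        "knockouts": sorted(set(knockout)),
        "crosstalk_on": sorted(flag_ids),
        "gap_fillers": gap_fillers,
    }
    (out / "run_config.json").write_text(json.dumps(config_echo, indent=2))
    click.echo(f"wrote {len(results)} step(s) to {out}")


@cli.command()
@click.option(
    "--scenario",
    type=click.Choice(["rgt2snf3", "tpk-bcy1", "snf1"]),
    required=True,
)
@click.option("--out", type=click.Path(file_okay=False), required=True)
def sweep(scenario, out):
    """Exhaustive crosstalk-combination sweep for a knockout scenario."""
    from . import analysis
    from .yeast_model import RGT2_SNF3_KO, SNF1_KO, TPK_BCY1_KO

    label = {"rgt2snf3": RGT2_SNF3_KO, "tpk-bcy1": TPK_BCY1_KO, "snf1": SNF1_KO}[scenario]
    definition = build_wt_model("glucose")
    scen = analysis.packaged_scenario(label, definition)
    table = analysis.crosstalk_sweep(scen, definition)
    score = analysis.restoration_report(table)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "sweep.tsv", sep="\t", index=False)
    summary = {
        "scenario": label,
        "condition": scen.condition.label(),
        "rows": len(table),
        "wt_like_rows": int((table["classification"] == analysis.WT_LIKE).sum()),
        "fraction_wt_like_when_active": {str(k): v for k, v in score.fraction.items()},
        "restoring_crosstalks": sorted(score.restoring),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    click.echo(json.dumps(summary, indent=2))


@cli.command()
def validate():
    """Re-run the packaged behavioral oracles; exit non-zero on failure."""
    from . import validation

    failures = validation.run_validation_suite()
    if failures:
        click.echo(json.dumps({"status": "fail", "failures": failures}, indent=2))
        sys.exit(1)
    click.echo(json.dumps({"status": "ok"}))


@cli.command("export-model")
@click.option("--model", type=click.Choice(["glucose", "full"]), default="glucose", show_default=True)
@click.option("--format", "fmt", type=click.Choice(["yaml", "json"]), default="yaml", show_default=True)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
def export_model(model, fmt, out):
    """Write the packaged model definition as a structured document."""
    definition = build_glucose_model() if model == "glucose" else build_full_model()
    doc = model_to_document(definition)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "yaml":
        out.write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=False))
    else:
        out.write_text(json.dumps(doc, indent=2))
    click.echo(f"wrote {out}")
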