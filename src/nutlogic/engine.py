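"""Vector-state rule-based Boolean kernel.

Components carry small state vectors rather than a single activity bit:
proteins have presence, localization, phosphorylation, nucleotide loading
(GDP/GTP) and DNA-binding fields; metabolites have presence and
localization; complex-formation components have a single activity bit.
A rule is a guarded update: a Boolean condition over state atoms plus a
list of field assignments. Simulation repeatedly sweeps the active rule
list in document order with immediate effect until a full sweep changes
nothing — the logical steady state (LSS).

Update semantics are deterministic document-order sweeps. Packaged model
content is authored to be confluent (the LSS does not depend on rule
order), which is enforced by permutation tests rather than by the kernel.

Knockouts fix a component's presence bit to 0: the component is never
modified, and any rule whose condition requires one of its fields to be
non-default can no longer fire. Conditions that test for *absence*
(e.g. ``presence != 1``) still evaluate against the zeroed vector.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .errors import ConfigurationError, ModelConsistencyError, OscillationError

# ---------------------------------------------------------------------------
# field domains

PROTEIN_LOCALIZATIONS = ("membrane", "cytosol", "nucleus")
METABOLITE_LOCALIZATIONS = ("extracellular", "cytosol", "nucleus")
BINARY = (0, 1)

PROTEIN_FIELDS = ("presence", "localization", "phosphorylation", "nucleotide", "dna_bound")
METABOLITE_FIELDS = ("presence", "localization")
COMPLEX_FIELDS = ("active",)

KIND_FIELDS = {
    "protein": PROTEIN_FIELDS,
    "metabolite": METABOLITE_FIELDS,
    "complex": COMPLEX_FIELDS,
}


def field_domain(kind: str, fieldname: str):
    """Return the tuple of admissible values for a field of a component kind."""
    if fieldname not in KIND_FIELDS[kind]:
        raise ModelConsistencyError(f"field {fieldname!r} does not exist for kind {kind!r}")
    if fieldname == "localization":
        return PROTEIN_LOCALIZATIONS if kind == "protein" else METABOLITE_LOCALIZATIONS
    return BINARY


# ---------------------------------------------------------------------------
# component state vectors


@dataclass
class ProteinState:
    """Six-entry state vector of a protein component.

    ``phosphorylation`` is a single regulatory-site bit whose meaning
    (activating or inhibitory mark) is fixed per protein by the rules that
    read it.  ``nucleotide`` is 1 for GTP-loaded, 0 for GDP/unloaded.
    """

    name: str
    presence: int = 1
    localization: str = "cytosol"
    phosphorylation: int = 0
    nucleotide: int = 0
    dna_bound: int = 0

    kind = "protein"


@dataclass
class MetaboliteState:
    name: str
    presence: int = 1
    localization: str = "cytosol"

    kind = "metabolite"


@dataclass
class ComplexState:
    name: str
    active: int = 0

    kind = "complex"


ComponentState = ProteinState | MetaboliteState | ComplexState


# ---------------------------------------------------------------------------
# conditions


@dataclass(frozen=True)
class Atom:
    """A single comparison against one field of one component."""

    component: str
    field: str
    value: object
    op: str = "eq"  # "eq" | "ne"

    def evaluate(self, state: "ModelState") -> bool:
        actual = getattr(state[self.component], self.field)
        return (actual == self.value) if self.op == "eq" else (actual != self.value)

    def atoms(self) -> Iterator["Atom"]:
        yield self


@dataclass(frozen=True)
class And:
    children: tuple

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))

    def evaluate(self, state: "ModelState") -> bool:
        return all(c.evaluate(state) for c in self.children)

    def atoms(self) -> Iterator[Atom]:
        for c in self.children:
            yield from c.atoms()


@dataclass(frozen=True)
class Or:
    children: tuple

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))

    def evaluate(self, state: "ModelState") -> bool:
        return any(c.evaluate(state) for c in self.children)

    def atoms(self) -> Iterator[Atom]:
        for c in self.children:
            yield from c.atoms()


@dataclass(frozen=True)
class Not:
    child: object

    def evaluate(self, state: "ModelState") -> bool:
        return not self.child.evaluate(state)

    def atoms(self) -> Iterator[Atom]:
        yield from self.child.atoms()


Condition = Atom | And | Or | Not

# condition-building shorthand used by the packaged model content
def present(name: str) -> Atom:
    return Atom(name, "presence", 1)


def absent(name: str) -> Atom:
    return Atom(name, "presence", 0)


def phos(name: str, value: int = 1) -> Atom:
    return Atom(name, "phosphorylation", value)


def gtp(name: str, value: int = 1) -> Atom:
    return Atom(name, "nucleotide", value)


def active(name: str, value: int = 1) -> Atom:
    return Atom(name, "active", value)


def located(name: str, compartment: str) -> Atom:
    return Atom(name, "localization", compartment)


# ---------------------------------------------------------------------------
# rules


@dataclass(frozen=True)
class Effect:
    component: str
    field: str
    value: object


@dataclass(frozen=True)
class Rule:
    """A guarded state update with provenance metadata.

    ``rule_class`` is one of ``base``, ``gap_filler`` or ``crosstalk``;
    crosstalk rules additionally carry the integer id of their registry
    entry.  ``citation`` holds the PubMed id(s) of the literature the
    reaction was curated from (empty for hypothetical gap fillers).
    """

    id: str
    pathway: str
    condition: Condition
    effects: tuple
    rule_class: str = "base"
    crosstalk_id: Optional[int] = None
    citation: str = ""

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))
        if self.rule_class == "crosstalk" and self.crosstalk_id is None:
            raise ModelConsistencyError(f"crosstalk rule {self.id!r} lacks a crosstalk_id")
        if self.rule_class != "crosstalk" and self.crosstalk_id is not None:
            raise ModelConsistencyError(
                f"rule {self.id!r} of class {self.rule_class!r} must not carry a crosstalk_id"
            )


# ---------------------------------------------------------------------------
# model definition


@dataclass(frozen=True)
class ComponentSpec:
    """Roster row: identity, kind, pathway table and default compartment."""

    name: str
    kind: str
    pathway: str
    default_localization: Optional[str] = None
    is_unknown: bool = False


@dataclass(frozen=True)
class CrosstalkEntry:
    """One registry entry: a pathway-connecting reaction that can be
    switched on or off as a complementary model input."""

    id: int
    components: tuple
    description: str
    rules: tuple
    citation: str = ""
    wt_required: bool = False
    sweepable: bool = True


@dataclass(frozen=True)
class InputCondition:
    """Nutrient availability: each input metabolite present (1) or absent (0).

    ``nitrogen`` is ignored by models that do not include the nitrogen
    input (the glucose-only reconstruction).
    """

    glucose: int
    nitrogen: Optional[int] = None

    def __post_init__(self):
        if self.glucose not in BINARY:
            raise ConfigurationError(f"glucose must be 0 or 1, got {self.glucose!r}")
        if self.nitrogen is not None and self.nitrogen not in BINARY:
            raise ConfigurationError(f"nitrogen must be 0 or 1, got {self.nitrogen!r}")

    def opposite(self) -> "InputCondition":
        return InputCondition(
            1 - self.glucose,
            None if self.nitrogen is None else 1 - self.nitrogen,
        )

    def label(self) -> str:
        parts = [f"glucose={self.glucose}"]
        if self.nitrogen is not None:
            parts.append(f"nitrogen={self.nitrogen}")
        return ", ".join(parts)


@dataclass(frozen=True)
class SimulationConfig:
    knockouts: frozenset = frozenset()
    crosstalk_flags: Mapping[int, int] = field(default_factory=dict)
    max_passes: int = 1000
    condition_sequence: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "crosstalk_flags", dict(self.crosstalk_flags))
        object.__setattr__(self, "condition_sequence", tuple(self.condition_sequence))
        if self.max_passes < 1:
            raise ConfigurationError("max_passes must be >= 1")


@dataclass(frozen=True)
class ModelDefinition:
    """Pathway-partitioned component roster, ordered rule list, crosstalk
    registry, gene map, input wiring, and the recorded knockout set."""

    name: str
    pathways: tuple                      # table order, e.g. ("Metab", "R2S3pw", ...)
    components: tuple                    # ComponentSpec, unique names
    rules: tuple                         # base + gap-filler rules, document order
    crosstalk: Mapping[int, CrosstalkEntry]
    gene_map: tuple = ()                 # GeneSpec (defined in yeast_model)
    inputs: Mapping[str, str] = field(default_factory=dict)  # metabolite -> attr
    knockouts: frozenset = frozenset()
    crosstalk_flags: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(self, "crosstalk", dict(self.crosstalk))
        object.__setattr__(self, "gene_map", tuple(self.gene_map))
        object.__setattr__(self, "inputs", dict(self.inputs))
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "crosstalk_flags", dict(self.crosstalk_flags))

    # -- lookups ------------------------------------------------------------

    @property
    def component_index(self) -> Mapping[str, ComponentSpec]:
        return {c.name: c for c in self.components}

    def spec(self, name: str) -> ComponentSpec:
        try:
            return self.component_index[name]
        except KeyError:
            raise ModelConsistencyError(f"unknown component {name!r}") from None

    def active_rules(self) -> tuple:
        """Base and gap-filler rules in document order, then the rules of
        every crosstalk entry whose flag is set, in ascending id order."""
        extra = []
        for ct_id in sorted(self.crosstalk):
            if self.crosstalk_flags.get(ct_id, 0):
                extra.extend(self.crosstalk[ct_id].rules)
        return self.rules + tuple(extra)

    def validate(self) -> None:
        """Raise ModelConsistencyError on duplicate names, dangling
        references or out-of-domain rule effects."""
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelConsistencyError(f"duplicate component names: {dupes}")
        index = self.component_index
        for c in self.components:
            if c.kind not in KIND_FIELDS:
                raise ModelConsistencyError(f"{c.name}: unknown kind {c.kind!r}")
            if c.pathway not in self.pathways:
                raise ModelConsistencyError(f"{c.name}: unknown pathway {c.pathway!r}")
            if c.kind != "complex":
                dom = field_domain(c.kind, "localization")
                if c.default_localization not in dom:
                    raise ModelConsistencyError(
                        f"{c.name}: default localization {c.default_localization!r} "
                        f"not in {dom}"
                    )
        all_rules = self.rules + tuple(
            itertools.chain.from_iterable(e.rules for e in self.crosstalk.values())
        )
        rule_ids = [r.id for r in all_rules]
        if len(rule_ids) != len(set(rule_ids)):
            dupes = sorted({i for i in rule_ids if rule_ids.count(i) > 1})
            raise ModelConsistencyError(f"duplicate rule ids: {dupes}")
        for rule in all_rules:
            for atom in rule.condition.atoms():
                if atom.component not in index:
                    raise ModelConsistencyError(
                        f"rule {rule.id!r}: condition references unknown "
                        f"component {atom.component!r}"
                    )
                kind = index[atom.component].kind
                dom = field_domain(kind, atom.field)  # raises on bad field
                if atom.value not in dom:
                    raise ModelConsistencyError(
                        f"rule {rule.id!r}: value {atom.value!r} outside domain "
                        f"of {atom.component}.{atom.field}"
                    )
            if not rule.effects:
                raise ModelConsistencyError(f"rule {rule.id!r} has no effects")
            for eff in rule.effects:
                if eff.component not in index:
                    raise ModelConsistencyError(
                        f"rule {rule.id!r}: effect targets unknown component "
                        f"{eff.component!r}"
                    )
                kind = index[eff.component].kind
                dom = field_domain(kind, eff.field)
                if eff.value not in dom:
                    raise ModelConsistencyError(
                        f"rule {rule.id!r}: effect value {eff.value!r} outside "
                        f"domain of {eff.component}.{eff.field}"
                    )
        for ct_id, entry in self.crosstalk.items():
            if entry.id != ct_id:
                raise ModelConsistencyError(f"crosstalk registry key {ct_id} != entry id {entry.id}")
            for rule in entry.rules:
                if rule.crosstalk_id != ct_id:
                    raise ModelConsistencyError(
                        f"rule {rule.id!r} carries crosstalk_id {rule.crosstalk_id}, "
                        f"registered under {ct_id}"
                    )
        for ko in self.knockouts:
            if ko not in index:
                raise ConfigurationError(f"unknown knockout component {ko!r}")
        for ct_id in self.crosstalk_flags:
            if ct_id not in self.crosstalk:
                raise ConfigurationError(f"unknown crosstalk id {ct_id}")
        for met in self.inputs:
            if met not in index or index[met].kind != "metabolite":
                raise ModelConsistencyError(f"input {met!r} is not a metabolite component")


# ---------------------------------------------------------------------------
# model state


class ModelState:
    """Mutable mapping of component name to state vector, with the
    pathway-partitioned table view used for reporting."""

    def __init__(self, definition: ModelDefinition, components: Mapping[str, ComponentState]):
        self._definition = definition
        self._components = dict(components)

    @property
    def definition(self) -> ModelDefinition:
        return self._definition

    def __getitem__(self, name: str) -> ComponentState:
        try:
            return self._components[name]
        except KeyError:
            raise ModelConsistencyError(f"unknown component {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._components

    def __iter__(self) -> Iterator[str]:
        return iter(self._components)

    def components(self) -> Iterator[ComponentState]:
        return iter(self._components.values())

    def tables(self) -> Mapping[str, list]:
        """Components grouped by pathway, in roster order. Each component
        appears in exactly one table."""
        out = {p: [] for p in self._definition.pathways}
        for spec in self._definition.components:
            out[spec.pathway].append(self._components[spec.name])
        return out

    def copy(self) -> "ModelState":
        return ModelState(self._definition, {n: replace(c) for n, c in self._components.items()})

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelState):
            return NotImplemented
        return self._components == other._components

    def diff(self, other: "ModelState") -> list:
        """Names of components whose state vectors differ."""
        return [n for n in self._components if self._components[n] != other._components[n]]

    def __repr__(self) -> str:
        return f"ModelState({self._definition.name!r}, {len(self._components)} components)"


# ---------------------------------------------------------------------------
# operations


def _new_component(spec: ComponentSpec) -> ComponentState:
    if spec.kind == "protein":
        return ProteinState(spec.name, localization=spec.default_localization)
    if spec.kind == "metabolite":
        return MetaboliteState(spec.name, localization=spec.default_localization)
    return ComplexState(spec.name)


def default_state(
    definition: ModelDefinition,
    condition: Optional[InputCondition] = None,
) -> ModelState:
    """Canonical start state.

    Every component is present except recorded knockouts; all
    phosphorylation / nucleotide / DNA-binding fields are 0; complexes are
    inactive; localization follows the roster default; input metabolites
    are set from ``condition`` when given.
    """
    for ko in definition.knockouts:
        if ko not in definition.component_index:
            raise ConfigurationError(f"unknown knockout component {ko!r}")
    components = {}
    for spec in definition.components:
        comp = _new_component(spec)
        if spec.name in definition.knockouts:
            comp.presence = 0
        components[spec.name] = comp
    state = ModelState(definition, components)
    if condition is not None:
        set_inputs(state, condition)
    return state


def set_inputs(state: ModelState, condition: InputCondition) -> None:
    """Overwrite the input metabolite presence bits in place."""
    for metabolite, attr in state.definition.inputs.items():
        value = getattr(condition, attr)
        if value is None:
            raise ConfigurationError(
                f"model {state.definition.name!r} requires an explicit "
                f"{attr!r} input value"
            )
        state[metabolite].presence = value


def eval_condition(state: ModelState, condition: Condition) -> bool:
    """Truth of a condition expression under standard AND/OR/NOT semantics.

    Evaluation is side-effect free; dangling references raise
    ModelConsistencyError (via state lookup)."""
    return condition.evaluate(state)


def apply_rule(state: ModelState, rule: Rule, knockouts: Iterable[str] = ()) -> bool:
    """Apply one rule in place; return whether any field actually changed.

    Knocked-out components are never modified.  A component whose presence
    bit is 0 is inert: no other field of it may change.
    """
    knockouts = frozenset(knockouts)
    if not eval_condition(state, rule.condition):
        return False
    changed = False
    for eff in rule.effects:
        if eff.component in knockouts:
            continue
        target = state[eff.component]
        if getattr(target, "presence", 1) == 0 and eff.field != "presence":
            continue
        if getattr(target, eff.field) != eff.value:
            setattr(target, eff.field, eff.value)
            changed = True
    return changed


def find_lss(
    definition: ModelDefinition,
    state: ModelState,
    config: Optional[SimulationConfig] = None,
    rule_order: Optional[Sequence[Rule]] = None,
) -> ModelState:
    """Sweep the active rule list until a full sweep changes nothing.

    Returns the logical steady state (a fixpoint of every active rule).
    ``rule_order`` overrides the document order, which is used by the
    confluence permutation tests.  Raises OscillationError if no fixpoint
    is found within ``max_passes`` sweeps.
    """
    config = config or SimulationConfig()
    rules = tuple(rule_order) if rule_order is not None else definition.active_rules()
    state = state.copy()
    knockouts = definition.knockouts | config.knockouts
    traces = []
    for _ in range(config.max_passes):
        changes = []
        for rule in rules:
            if apply_rule(state, rule, knockouts):
                changes.append(rule.id)
        if not changes:
            return state
        traces.append(changes)
    raise OscillationError(
        f"no logical steady state within {config.max_passes} sweeps "
        f"(model {definition.name!r}); last two sweep traces attached",
        trace=traces[-2:],
    )


def configure_model(
    definition: ModelDefinition,
    knockouts: Iterable[str] = (),
    crosstalk_flags: Optional[Mapping[int, int]] = None,
) -> ModelDefinition:
    """Record a knockout set and crosstalk flag vector on the definition.

    The flagged crosstalk rules are appended after base and gap-filler
    rules in ascending crosstalk id order (see ``active_rules``).
    """
    knockouts = frozenset(knockouts)
    crosstalk_flags = dict(crosstalk_flags or {})
    index = definition.component_index
    for ko in knockouts:
        if ko not in index:
            raise ConfigurationError(f"unknown knockout component {ko!r}")
    for ct_id, flag in crosstalk_flags.items():
        if ct_id not in definition.crosstalk:
            raise ConfigurationError(f"unknown crosstalk id {ct_id}")
        if flag not in BINARY:
            raise ConfigurationError(f"crosstalk flag for id {ct_id} must be 0 or 1")
    return replace(definition, knockouts=knockouts, crosstalk_flags=crosstalk_flags)


def run_protocol(
    definition: ModelDefinition,
    config: SimulationConfig,
) -> list:
    """Sequentially switch between input conditions.

    The first step starts from the canonical default state; every later
    step starts from the previous LSS with only the input metabolite bits
    changed.  Returns one ``(InputCondition, ModelState)`` pair per step.
    """
    if not config.condition_sequence:
        raise ConfigurationError("condition_sequence must not be empty")
    definition = configure_model(
        definition,
        knockouts=definition.knockouts | config.knockouts,
        crosstalk_flags={**definition.crosstalk_flags, **config.crosstalk_flags},
    )
    results = []
    state = default_state(definition, config.condition_sequence[0])
    for step, condition in enumerate(config.condition_sequence):
        set_inputs(state, condition)
        try:
            state = find_lss(definition, state, config)
        except OscillationError as err:
            err.step = step
            raise
        results.append((condition, state))
        state = state.copy()
    return results


def predict(
    definition: ModelDefinition,
    condition: InputCondition,
    config: Optional[SimulationConfig] = None,
) -> ModelState:
    """LSS prediction for a single target condition.

    Signaling networks sense *changes*, so the model is first equilibrated
    at the opposite nutrient condition and then switched to the target;
    the second LSS is reported.
    """
    base = config or SimulationConfig()
    seq = (condition.opposite(), condition)
    cfg = replace(base, condition_sequence=seq)
    return run_protocol(definition, cfg)[-1][1]


def permuted_rule_order(definition: ModelDefinition, rng) -> tuple:
    """A random permutation of the active rule list (for confluence checks)."""
    rules = list(definition.active_rules())
    rng.shuffle(rules)
    return tuple(rules)
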