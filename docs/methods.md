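# Methods

## Model formalism

Each component carries a typed state vector.  Proteins:
`(presence, localization ∈ {membrane, cytosol, nucleus}, phosphorylation,
nucleotide, dna_bound)`, all non-localization fields binary.  Metabolites:
`(presence, localization ∈ {extracellular, cytosol, nucleus})`.  Complex
formation (PKA holoenzyme, TORC1) is a single activity bit.  The
`phosphorylation` bit is a *regulatory mark* whose sign is defined per
protein by the rules that read it: it means "active" for Snf1, Msn2/4 and
Gis1, "inactivated" for Mth1/Std1, Yak1, Rim15 and Sak1,
"hyper-phosphorylated activator form" for Rgt1, and "PP1 holoenzyme
active" on Reg1.  G-proteins (Gpa2, Ras1/2) use the nucleotide bit
(1 = GTP).

A rule is `IF <Boolean expression over state atoms> THEN <ordered field
assignments>`.  Rules are classed `base` (literature reconstruction),
`gap_filler` (hypothetical additions required for condition switching) or
`crosstalk` (registry entries that can be toggled per run).  Every rule
carries a PubMed id tag; gap fillers are tagged `hypothetical`.

## Update scheme and confluence

Reactions execute asynchronously with immediate effect: the simulator
sweeps the active rule list in document order, applying every satisfied
rule in place, and stops when a full sweep changes nothing (the logical
steady state).  To make this reproducible we fix the document order and
require the packaged rule content to be *confluent*: the LSS must be
invariant under arbitrary rule orderings.  This is achieved by authoring
rules in complementary pairs gated on the (constant-per-step) nutrient
inputs, so that within one condition the writers of any field agree at
the fixpoint, and the dependency graph per condition is effectively
acyclic.  Confluence is not a kernel guarantee but a tested property:
every packaged scenario is re-simulated under 100 random rule
permutations (seeded) and must reproduce the reference LSS bit for bit.
A state that fails to stabilize within `max_passes` sweeps (default
1000; the packaged model needs ≤ ~5) raises an oscillation error carrying
the last two sweep traces.

## Initial state and protocols

The canonical start state has every component present (except
knockouts), all modification fields 0, complexes inactive and roster
default compartments; input metabolites are set per condition.  Because
signaling networks sense *changes*, single-condition predictions always
pre-equilibrate at the opposite condition first and report the second
LSS.  In condition sequences, each LSS seeds the next step with only the
input metabolite bits changed.

Knockouts zero the presence bit; the component is never modified and any
rule requiring one of its fields to be non-default cannot fire.  Atoms
are evaluated against the zeroed vector, so conditions testing *absence*
still work.  Consequence: a rule that needs a knocked-out kinase to be
*active* must test `present AND phosphorylated`, which the packaged
content does throughout.

## Packaged content decisions

The published description fixes the counts (61 base rules, 6 gap
conditions, 10 TOR rules, 48/67-component rosters, 19 genes) and the
input/output behavior, but not the exact per-rule decomposition.  The
packaged tables are therefore authored to meet the counts and all
behavioral oracles
simultaneously.  Choices worth knowing:

* **Crosstalks 7 and 9 are glucose-gated, not PKA-state-gated.**  They
  represent the glucose-activated PKA *pathway* requirement for PP1
  (Glc7-Reg1) activation and Rgt1 phosphorylation.  Gating them on the
  PKA complex bit would contradict the reported PKA-complex-deletion
  phenotype (only the PDS group deviates): with `Tpk1-3`/`Bcy1` deleted,
  Snf1 dephosphorylation and HXT expression still follow glucose.
* **A base Rgt1 hyper-phosphorylation rule exists** (gated on
  inactivated Mth1/Std1 and inactive Snf1), because the
  literature-only model must already reproduce the *first* condition it
  is put in; the gap-filling analysis shows what breaks on *switching*.
  Crosstalk 9 adds the PKA-dependent route.
* **Crosstalk 1** is implemented as Snf1-activity-gated Mth1/Std1
  inactivation (fires when Snf1 is present and inactive,
  sensor-independently): a literal "prevents inactivation" reading could
  not restore the sensor deletion, which the crosstalk demonstrably does.
* **Msn2/4 phosphorylation is the activating mark** (set by active
  Rim15/Yak1 without glucose, removed by Xxx4 with glucose).  The two
  writers are gated on opposite glucose states, which keeps the content
  confluent and reproduces the STRE-off/PDS-on split of the PKA-complex
  deletion.
* **Mth1 has no dephosphorylation rule** — the gap-filling table lists
  only Std1 and Rgt1 — so its inactivation mark persists after the first
  glucose exposure.  The gene readout never consults Mth1 directly and
  repeated switching is stable from the first revisit of each condition.
* **TOR crosstalk identities** (registry ids 10–13) are assigned as
  Sch9→Rim15, TORC1→Rim15, Snf1→Par32 and Snf1→Gln3 — four reactions
  converging on Rim15 and Gln3.  Snf1- and TOR-dependent Gln3
  phosphorylation are treated as the same regulatory mark; the Snf1→Gln3
  entry also phosphorylates the TORC1 subunit Kog1, so Gln3 localization
  (the NCR readout) follows TORC1 activity.  The TOR gap fillers
  Xxx5/Xxx6 dephosphorylate Kog1/Par32 when Snf1 is inactive and only
  matter when that crosstalk is on.
* **Roster stand-ins** where the source names none: the third glucose
  metabolite is ATP (Cyr1 substrate), the NCR gene set is
  {GAP1, MEP2, DAL5, PUT1, GDH2, CAN1}, and the glucose/TOR-shared
  proteins are {Sch9, Rim15, Snf1}, reconciling 45 + 15 − 3 = 57 known
  proteins.  Hxt1–Hxt17 are collapsed into one transporter component
  (`HXTs`); HXK2 appears both as a protein and as an Rgt1-regulated
  target gene.

## Gene readout

A gene is ON at an LSS iff its regulator condition holds: SUC2 unless
nuclear DNA-bound Mig1 with Ssn6-Tup1; HXT/HXK unless unphosphorylated
DNA-bound Rgt1 with Ssn6-Tup1; STRE iff nuclear phosphorylated Msn2 or
Msn4; PDS iff activated Gis1; NCR iff nuclear DNA-bound Gln3.  Within
the packaged model all members of a group share one status at every LSS;
a disagreement raises an internal-consistency error.

## Analyses

*Knockout panel*: per perturbation × condition, the group pattern and
its deviation set from the wild-type prediction.  *Crosstalk sweep*: the
2⁷ = 128 on/off combinations of the testable reactions {1,2,3,4,5,6,8}
(7 and 9 are wild-type requirements and stay on), each simulated
independently and classified WT-like (equals the wild-type reference on
all groups), perturbed-like (equals the all-off baseline) or other; ties
resolve to WT-like and cannot occur for the packaged scenarios.  A
reaction *restores* a scenario when its restoration fraction is exactly
1.0 over the 64 combinations it is active in.  *Gap diagnostics*: both
switch directions are run and the groups mismatching the expected
pattern after the switch are reported together with the components whose
state failed to reset relative to a fresh simulation of the same
condition.

## Serialization and reporting

Models serialize to a versioned YAML document (components, rules with
explicit and/or/not/atom condition trees, crosstalk registry, gene map,
flags); loading re-validates and round-trips losslessly, and the shipped
`data/*.yaml` documents are asserted equal to the built definitions.
LSS output is written as one TSV table per pathway (metabolites and
shared/miscellaneous proteins have their own tables), a per-gene status
file, and a deterministic SVG schematic per pathway (membrane band,
cytosol, nucleus; modification dots; DNA stems; greyed boxes for deleted
components).

## Limitations

The model is discrete, deterministic and semi-quantitative: no kinetics,
no graded cAMP dynamics, no stochastic or probabilistic semantics, no
attractor/cycle enumeration (non-stabilizing configurations are an
error by design).  Mig2 and the individual hexose transporters are not
resolved; the TOR extension covers only the Sch9 and PP2A/Gln3 branches.
The hypothetical phosphatases Xxx1–Xxx6 are gap fillers, not identified
enzymes, and the exact rule decomposition is a count-constrained
reconstruction, so agreement with the published censuses and phenotypes
does not imply per-rule mechanistic identity.
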