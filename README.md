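# nutlogic

Rule-based Boolean logic modeling of the *Saccharomyces cerevisiae*
nutrient-signaling network: the Snf3/Rgt2 hexose-sensing, Snf1 (glucose
repression) and cAMP-PKA pathways, with an optional extension for the
nitrogen-sensing TOR pathway.

Classical Boolean networks give every node a single on/off bit.  Signaling
proteins, however, differ in presence, compartment, phosphorylation,
GDP/GTP loading and DNA binding at the same time.  `nutlogic` therefore
assigns each protein a state *vector*

```
(name, presence, localization, phosphorylation, nucleotide, dna_bound)
```

(metabolites carry only presence and localization; complex-formation
components such as the PKA holoenzyme and TORC1 a single activity bit).
Reactions are guarded updates — `IF <condition over state atoms> THEN
<field assignments>` — connected with AND/OR/NOT.  Simulation sweeps the
rule list with immediate effect until no rule changes anything: the
**logical steady state (LSS)**.  Knockouts fix a component's presence bit
to 0 and exclude it from every reaction.  Crosstalk reactions between
pathways can be switched on and off individually, and the model can
switch between nutrient conditions sequentially, using each LSS as the
start state for the next condition.

The packaged model contains:

* a 48-component glucose-signaling reconstruction (45 proteins,
  3 metabolites) governed by 61 literature-curated rules, each tagged
  with its PubMed id;
* six gap-filling conditions — four hypothetical phosphatases
  (`Xxx1`–`Xxx4`) and two wild-type-required crosstalk reactions —
  without which the model reproduces the first nutrient condition but
  cannot *switch* between conditions;
* a registry of 9 glucose-era crosstalk reactions plus 4 TOR-era
  reactions converging on Rim15 and Gln3;
* the TOR extension (15 pathway proteins, TORC1, nitrogen input, 10
  rules, 2 further unknown phosphatases), for 67 components total;
* the 19-target-gene readout grouped as SUC / HXT / HXK / STRE / PDS /
  NCR.

Analyses built on top: in-silico knockout panels, exhaustive sweeps of
all 2⁷ = 128 on/off combinations of the testable crosstalk reactions
with WT-like / perturbed-like / other classification, restoration
scoring, and gap-filling diagnostics.

## Worked example

```python
from nutlogic import InputCondition, predict, configure_model
from nutlogic.yeast_model import build_wt_model, group_pattern
from nutlogic import analysis

wt = build_wt_model("glucose")          # gap fillers + crosstalks 7 and 9

for g in (1, 0):
    print(g, group_pattern(predict(wt, InputCondition(g))))
```

prints the wild-type expression truth table (1 = expressed):

```
1 {'SUC': 0, 'HXT': 1, 'HXK': 1, 'STRE': 0, 'PDS': 0}
0 {'SUC': 1, 'HXT': 0, 'HXK': 0, 'STRE': 1, 'PDS': 1}
```

i.e. with glucose the hexose transporter (HXT) and hexokinase (HXK)
genes are on while SUC2 and the stress programs are repressed; without
glucose the pattern inverts.  Deleting the two glucose sensors and
sweeping the crosstalk combinations:

```python
scenario = analysis.packaged_scenario("rgt2Δsnf3Δ", wt)
sweep = analysis.crosstalk_sweep(scenario, wt)
score = analysis.restoration_report(sweep)
print(len(sweep), (sweep.classification == "WT-like").sum(), sorted(score.restoring))
```

```
128 96 [1, 3]
```

Of the 128 crosstalk combinations, 96 restore the wild-type pattern —
exactly those in which crosstalk 1 (Snf1 gating of Mth1/Std1
inactivation) or crosstalk 3 (Reg1-Glc7 activation of Yck1/2) is active;
both are Snf1-to-Snf3/Rgt2 pathway connections, and each restores in all
64 combinations it participates in.  The same sweep for `snf1Δ` (no
glucose) or the PKA-complex deletion finds no restoring combination.

The same is available from the shell:

```sh
nutlogic simulate --glucose-sequence 0,1 --knockout Snf1 --out run/
nutlogic sweep --scenario rgt2snf3 --out sweep/
nutlogic validate
nutlogic export-model --model full --format yaml --out full.yaml
```

`simulate` writes per-pathway LSS state tables (TSV), an SVG schematic
of each pathway (compartments, modification marks, DNA binding) and the
per-gene status file; `validate` re-runs the packaged behavioral oracles
and exits non-zero on any mismatch.

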