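"""Packaged nutrient-signaling model of S. cerevisiae.

Content: component rosters for the Snf3/Rgt2 (hexose sensing), Snf1
(glucose repression), cAMP-PKA and TOR (nitrogen) pathways; the 61-rule
base glucose rule table; the six gap-filling conditions (four hypothetical
phosphatases Xxx1-Xxx4 plus two wild-type-required crosstalk reactions);
the crosstalk registry (nine glucose-era reactions, four TOR-era reactions
converging on Rim15 and Gln3); and the 19-gene readout map.

Signal-flow summary
-------------------
Glucose present: the membrane sensors Snf3/Rgt2 activate the casein
kinases Yck1/2, which (with the SCF component Grr1) mark the corepressors
Mth1/Std1 for inactivation; Rgt1 then becomes hyper-phosphorylated
(PKA-pathway dependent, crosstalk 9) and the HXT/HXK genes are expressed.
PKA-dependent activation of the Glc7-Reg1 (PP1) phosphatase (crosstalk 7)
dephosphorylates Snf1; unphosphorylated Mig1 enters the nucleus and
represses SUC2 with Ssn6-Tup1.  Gpr1/Gpa2 and Cdc25-Ras-GTP stimulate
Cyr1 (adenylate cyclase), cAMP accumulates, the PKA holoenzyme
(Tpk1/2/3 + Bcy1) inactivates Yak1 and Rim15, switching off the STRE
(Msn2/4) and PDS (Gis1) stress programs; Xxx4 dephosphorylates Msn2/4.

No glucose: Xxx1-Xxx3 reset Std1/Rgt1, Yak1/Rim15 and PP1; Sak1 activates
Snf1, Mig1 is phosphorylated and leaves the nucleus (SUC2 on); cAMP is
degraded by Pde1/2 and Ras unloaded by Ira1/2, PKA falls inactive, active
Rim15/Yak1 phosphorylate Msn2/4 (activating) and Rim15 activates Gis1
(STRE and PDS on).

Nitrogen present: TORC1 (Tor1-Kog1-Lst8-Tco89) is active, phosphorylates
Sch9 and (with Ure2) keeps Gln3 phosphorylated and cytosolic, silencing
the NCR genes.  Nitrogen absent: PP2A/Sit4 dephosphorylate Gln3, which
enters the nucleus and activates NCR genes.  The Snf1-to-Gln3 crosstalk
(active Snf1 phosphorylates Gln3 and the TORC1 subunit Kog1) drives NCR
expression under glucose limitation even when nitrogen is plentiful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

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
    located,
    phos,
    present,
    gtp,
    active,
    predict,
)
from .errors import ConfigurationError, ModelConsistencyError

# ---------------------------------------------------------------------------
# shorthand

G1 = Atom("Glucose", "presence", 1)
G0 = Atom("Glucose", "presence", 0)
N1 = Atom("Nitrogen", "presence", 1)
N0 = Atom("Nitrogen", "presence", 0)

HYPOTHETICAL = "hypothetical (gap filling)"


def _eff(component: str, fieldname: str, value) -> Effect:
    return Effect(component, fieldname, value)


# ---------------------------------------------------------------------------
# component rosters

PATHWAYS_GLUCOSE = ("Metab", "R2S3pw", "Snf1pw", "PKApw", "Miscl")
PATHWAYS_FULL = ("Metab", "R2S3pw", "Snf1pw", "PKApw", "TORpw", "Miscl")


def _p(name, pathway, loc):
    return ComponentSpec(name, "protein", pathway, loc)


def _m(name, loc):
    return ComponentSpec(name, "metabolite", "Metab", loc)


def _x(name, pathway="Miscl"):
    return ComponentSpec(name, "protein", pathway, "cytosol", is_unknown=True)


METABOLITES_GLUCOSE = (
    _m("Glucose", "extracellular"),
    _m("cAMP", "cytosol"),
    _m("ATP", "cytosol"),
)

R2S3_PROTEINS = (
    _p("Snf3", "R2S3pw", "membrane"),
    _p("Rgt2", "R2S3pw", "membrane"),
    _p("Yck1", "R2S3pw", "membrane"),
    _p("Yck2", "R2S3pw", "membrane"),
    _p("Mth1", "R2S3pw", "cytosol"),
    _p("Std1", "R2S3pw", "cytosol"),
    _p("Grr1", "R2S3pw", "cytosol"),
    _p("Rgt1", "R2S3pw", "nucleus"),
    _p("HXTs", "R2S3pw", "membrane"),  # Hxt1-Hxt17 collapsed to one transporter
)

SNF1_PROTEINS = (
    _p("Snf1", "Snf1pw", "cytosol"),
    _p("Snf4", "Snf1pw", "cytosol"),
    _p("Gal83", "Snf1pw", "cytosol"),
    _p("Sip1", "Snf1pw", "cytosol"),
    _p("Sip2", "Snf1pw", "cytosol"),
    _p("Sak1", "Snf1pw", "cytosol"),
    _p("Reg1", "Snf1pw", "cytosol"),
    _p("Glc7", "Snf1pw", "cytosol"),
    _p("Mig1", "Snf1pw", "cytosol"),
    _p("Mig2", "Snf1pw", "nucleus"),
)

PKA_PROTEINS = (
    _p("Gpr1", "PKApw", "membrane"),
    _p("Gpa2", "PKApw", "membrane"),
    _p("Rgs2", "PKApw", "cytosol"),
    _p("Cdc25", "PKApw", "membrane"),
    _p("Sdc25", "PKApw", "membrane"),
    _p("Ras1", "PKApw", "membrane"),
    _p("Ras2", "PKApw", "membrane"),
    _p("Ira1", "PKApw", "cytosol"),
    _p("Ira2", "PKApw", "cytosol"),
    _p("Cyr1", "PKApw", "membrane"),
    _p("Srv2", "PKApw", "membrane"),
    _p("Pde1", "PKApw", "cytosol"),
    _p("Pde2", "PKApw", "cytosol"),
    _p("Tpk1", "PKApw", "cytosol"),
    _p("Tpk2", "PKApw", "cytosol"),
    _p("Tpk3", "PKApw", "cytosol"),
    _p("Bcy1", "PKApw", "cytosol"),
    _p("Yak1", "PKApw", "cytosol"),
    _p("Rim15", "PKApw", "cytosol"),
    _p("Msn2", "PKApw", "cytosol"),
    _p("Msn4", "PKApw", "cytosol"),
    _p("Gis1", "PKApw", "nucleus"),
)

MISC_PROTEINS = (
    _p("Ssn6", "Miscl", "cytosol"),
    _p("Tup1", "Miscl", "cytosol"),
    _p("Hxk2", "Miscl", "nucleus"),
    _p("Sch9", "Miscl", "cytosol"),
)

PKA_COMPLEX = ComponentSpec("PKA", "complex", "PKApw")

GLUCOSE_GAP_COMPONENTS = (_x("Xxx1"), _x("Xxx2"), _x("Xxx3"), _x("Xxx4"))

# 12 TOR-pathway proteins new to the full model; Sch9, Rim15 and Snf1 are
# shared with the glucose rosters, giving the 15-protein TOR pathway.
TOR_PROTEINS_NEW = (
    _p("Tor1", "TORpw", "membrane"),
    _p("Kog1", "TORpw", "membrane"),
    _p("Lst8", "TORpw", "membrane"),
    _p("Tco89", "TORpw", "membrane"),
    _p("Tap42", "TORpw", "cytosol"),
    _p("Sit4", "TORpw", "cytosol"),
    _p("Pph21", "TORpw", "cytosol"),
    _p("Pph22", "TORpw", "cytosol"),
    _p("Tpd3", "TORpw", "cytosol"),
    _p("Gln3", "TORpw", "cytosol"),
    _p("Ure2", "TORpw", "cytosol"),
    _p("Par32", "TORpw", "cytosol"),
)

TOR_SHARED_PROTEINS = ("Sch9", "Rim15", "Snf1")
TOR_PATHWAY_PROTEINS = tuple(p.name for p in TOR_PROTEINS_NEW) + TOR_SHARED_PROTEINS

TORC1_COMPLEX = ComponentSpec("TORC1", "complex", "TORpw")

TOR_GAP_COMPONENTS = (_x("Xxx5"), _x("Xxx6"))

NITROGEN = _m("Nitrogen", "extracellular")


# ---------------------------------------------------------------------------
# base glucose rule table (61 rules)


def _rule(rid, pathway, condition, effects, citation, rule_class="base", crosstalk_id=None):
    return Rule(
        id=rid,
        pathway=pathway,
        condition=condition,
        effects=tuple(effects),
        rule_class=rule_class,
        crosstalk_id=crosstalk_id,
        citation=citation,
    )


def _base_glucose_rules() -> tuple:
    r = []
    # -- Rgt2/Snf3 pathway ---------------------------------------------------
    r += [
        _rule("r01", "R2S3pw", G1, [_eff("Snf3", "phosphorylation", 1)], "8901598"),
        _rule("r02", "R2S3pw", G0, [_eff("Snf3", "phosphorylation", 0)], "8901598"),
        _rule("r03", "R2S3pw", G1, [_eff("Rgt2", "phosphorylation", 1)], "8901598"),
        _rule("r04", "R2S3pw", G0, [_eff("Rgt2", "phosphorylation", 0)], "8901598"),
        _rule("r05", "R2S3pw", And(G1, phos("Snf3")), [_eff("Yck1", "phosphorylation", 1)], "14755054"),
        _rule("r06", "R2S3pw", And(G1, phos("Rgt2")), [_eff("Yck1", "phosphorylation", 1)], "14755054"),
        _rule("r07", "R2S3pw", And(G1, phos("Snf3")), [_eff("Yck2", "phosphorylation", 1)], "14755054"),
        _rule("r08", "R2S3pw", And(G1, phos("Rgt2")), [_eff("Yck2", "phosphorylation", 1)], "14755054"),
        _rule("r09", "R2S3pw", G0, [_eff("Yck1", "phosphorylation", 0)], "14755054"),
        _rule("r10", "R2S3pw", G0, [_eff("Yck2", "phosphorylation", 0)], "14755054"),
        _rule("r11", "R2S3pw", And(phos("Yck1"), present("Grr1")), [_eff("Mth1", "phosphorylation", 1)], "12024050"),
        _rule("r12", "R2S3pw", And(phos("Yck2"), present("Grr1")), [_eff("Mth1", "phosphorylation", 1)], "12024050"),
        _rule("r13", "R2S3pw", And(phos("Yck1"), present("Grr1")), [_eff("Std1", "phosphorylation", 1)], "12024050"),
        _rule("r14", "R2S3pw", And(phos("Yck2"), present("Grr1")), [_eff("Std1", "phosphorylation", 1)], "12024050"),
        # Rgt1 hyper-phosphorylation: requires inactivated corepressors and
        # an inactive Snf1 pathway (glucose-replete signaling context).
        _rule(
            "r15",
            "R2S3pw",
            And(phos("Mth1"), phos("Std1"), phos("Snf1", 0), present("Rgt1")),
            [_eff("Rgt1", "phosphorylation", 1)],
            "16847060",
        ),
        _rule("r16", "R2S3pw", present("Rgt1"), [_eff("Rgt1", "dna_bound", 1)], "12730235"),
        _rule("r17", "R2S3pw", present("Rgt1"), [_eff("Rgt1", "localization", "nucleus")], "12730235"),
    ]
    # -- Snf1 pathway --------------------------------------------------------
    r += [
        _rule(
            "s01",
            "Snf1pw",
            And(
                G0,
                present("Sak1"),
                phos("Sak1", 0),
                present("Snf4"),
                Or(present("Gal83"), present("Sip1"), present("Sip2")),
                present("Snf1"),
            ),
            [_eff("Snf1", "phosphorylation", 1)],
            "12748283",
        ),
        _rule(
            "s02",
            "Snf1pw",
            And(phos("Reg1"), present("Reg1"), present("Glc7"), present("Snf1")),
            [_eff("Snf1", "phosphorylation", 0)],
            "10757793",
        ),
        _rule(
            "s03",
            "Snf1pw",
            And(present("Snf1"), phos("Snf1"), present("Mig1")),
            [_eff("Mig1", "phosphorylation", 1)],
            "3526554",
        ),
        _rule(
            "s04",
            "Snf1pw",
            And(phos("Snf1", 0), phos("Reg1"), present("Reg1"), present("Glc7"), present("Mig1")),
            [_eff("Mig1", "phosphorylation", 0)],
            "28087654",
        ),
        _rule("s05", "Snf1pw", And(present("Mig1"), phos("Mig1", 0)), [_eff("Mig1", "localization", "nucleus")], "9585503"),
        _rule("s06", "Snf1pw", And(present("Mig1"), phos("Mig1", 0)), [_eff("Mig1", "dna_bound", 1)], "7544001"),
        _rule("s07", "Snf1pw", phos("Mig1"), [_eff("Mig1", "localization", "cytosol")], "9585503"),
        _rule("s08", "Snf1pw", phos("Mig1"), [_eff("Mig1", "dna_bound", 0)], "7544001"),
        _rule("s09", "Snf1pw", present("Mig2"), [_eff("Mig2", "localization", "nucleus")], "8649386"),
        _rule("s10", "Snf1pw", present("Mig2"), [_eff("Mig2", "dna_bound", 1)], "8649386"),
    ]
    # -- cAMP-PKA pathway ----------------------------------------------------
    r += [
        _rule("p01", "PKApw", G1, [_eff("Gpr1", "phosphorylation", 1)], "10848604"),
        _rule("p02", "PKApw", G0, [_eff("Gpr1", "phosphorylation", 0)], "10848604"),
        _rule("p03", "PKApw", And(present("Gpr1"), phos("Gpr1")), [_eff("Gpa2", "nucleotide", 1)], "9671033"),
        _rule("p04", "PKApw", And(phos("Gpr1", 0), present("Rgs2")), [_eff("Gpa2", "nucleotide", 0)], "10604476"),
        _rule("p05", "PKApw", And(G1, present("Cdc25")), [_eff("Ras1", "nucleotide", 1)], "2197982"),
        _rule("p06", "PKApw", And(G1, present("Sdc25")), [_eff("Ras1", "nucleotide", 1)], "2197982"),
        _rule("p07", "PKApw", And(G1, present("Cdc25")), [_eff("Ras2", "nucleotide", 1)], "2197982"),
        _rule("p08", "PKApw", And(G1, present("Sdc25")), [_eff("Ras2", "nucleotide", 1)], "2197982"),
        _rule("p09", "PKApw", And(G0, present("Ira1")), [_eff("Ras1", "nucleotide", 0)], "2164630"),
        _rule("p10", "PKApw", And(G0, present("Ira2")), [_eff("Ras1", "nucleotide", 0)], "2164630"),
        _rule("p11", "PKApw", And(G0, present("Ira1")), [_eff("Ras2", "nucleotide", 0)], "2164630"),
        _rule("p12", "PKApw", And(G0, present("Ira2")), [_eff("Ras2", "nucleotide", 0)], "2164630"),
        _rule(
            "p13",
            "PKApw",
            And(Or(gtp("Ras1"), gtp("Ras2")), present("Cyr1"), phos("Cyr1", 0), present("Srv2"), present("ATP")),
            [_eff("cAMP", "presence", 1)],
            "9671033",
        ),
        _rule(
            "p14",
            "PKApw",
            And(gtp("Gpa2"), present("Cyr1"), phos("Cyr1", 0), present("Srv2"), present("ATP")),
            [_eff("cAMP", "presence", 1)],
            "9671033",
        ),
        _rule("p15", "PKApw", And(G0, present("Pde1")), [_eff("cAMP", "presence", 0)], "9671033"),
        _rule("p16", "PKApw", And(G0, present("Pde2")), [_eff("cAMP", "presence", 0)], "9671033"),
        _rule(
            "p17",
            "PKApw",
            And(present("cAMP"), Or(present("Tpk1"), present("Tpk2"), present("Tpk3")), present("Bcy1")),
            [_eff("PKA", "active", 1)],
            "2832726",
        ),
        _rule("p18", "PKApw", absent_cAMP(), [_eff("PKA", "active", 0)], "2832726"),
        _rule("p19", "PKApw", And(active("PKA"), present("Yak1")), [_eff("Yak1", "phosphorylation", 1)], "15466424"),
        _rule("p20", "PKApw", And(active("PKA"), present("Rim15")), [_eff("Rim15", "phosphorylation", 1)], "14690591"),
        _rule(
            "p21",
            "PKApw",
            And(G0, present("Yak1"), phos("Yak1", 0), present("Msn2")),
            [_eff("Msn2", "phosphorylation", 1)],
            "18793336",
        ),
        _rule(
            "p22",
            "PKApw",
            And(G0, present("Rim15"), phos("Rim15", 0), present("Msn2")),
            [_eff("Msn2", "phosphorylation", 1)],
            "23122960",
        ),
        _rule(
            "p23",
            "PKApw",
            And(G0, present("Yak1"), phos("Yak1", 0), present("Msn4")),
            [_eff("Msn4", "phosphorylation", 1)],
            "18793336",
        ),
        _rule(
            "p24",
            "PKApw",
            And(G0, present("Rim15"), phos("Rim15", 0), present("Msn4")),
            [_eff("Msn4", "phosphorylation", 1)],
            "23122960",
        ),
        _rule("p25", "PKApw", And(present("Msn2"), phos("Msn2")), [_eff("Msn2", "localization", "nucleus")], "9472026"),
        _rule("p26", "PKApw", phos("Msn2", 0), [_eff("Msn2", "localization", "cytosol")], "9472026"),
        _rule("p27", "PKApw", And(present("Msn4"), phos("Msn4")), [_eff("Msn4", "localization", "nucleus")], "9472026"),
        _rule("p28", "PKApw", phos("Msn4", 0), [_eff("Msn4", "localization", "cytosol")], "9472026"),
        _rule(
            "p29",
            "PKApw",
            And(G0, present("Rim15"), phos("Rim15", 0), present("Gis1")),
            [_eff("Gis1", "phosphorylation", 1)],
            "10757793",
        ),
        _rule("p30", "PKApw", And(present("Rim15"), phos("Rim15")), [_eff("Gis1", "phosphorylation", 0)], "10757793"),
        _rule("p31", "PKApw", And(present("Gis1"), phos("Gis1")), [_eff("Gis1", "dna_bound", 1)], "10757793"),
        _rule("p32", "PKApw", phos("Gis1", 0), [_eff("Gis1", "dna_bound", 0)], "10757793"),
    ]
    # -- miscellaneous (general corepressors) --------------------------------
    r += [
        _rule("m01", "Miscl", present("Ssn6"), [_eff("Ssn6", "localization", "nucleus")], "7544001"),
        _rule("m02", "Miscl", present("Tup1"), [_eff("Tup1", "localization", "nucleus")], "7544001"),
    ]
    assert len(r) == 61, f"base glucose rule table must have 61 rules, found {len(r)}"
    return tuple(r)


def absent_cAMP() -> Atom:
    return Atom("cAMP", "presence", 0)


# ---------------------------------------------------------------------------
# gap fillers (hypothetical phosphatases Xxx1-Xxx4; Xxx5/Xxx6 for TOR)

GLUCOSE_GAP_RULES = (
    _rule(
        "gf1_Xxx1",
        "Miscl",
        And(G0, present("Xxx1")),
        [_eff("Std1", "phosphorylation", 0), _eff("Rgt1", "phosphorylation", 0)],
        HYPOTHETICAL,
        rule_class="gap_filler",
    ),
    _rule(
        "gf2_Xxx2",
        "Miscl",
        And(G0, present("Xxx2")),
        [_eff("Yak1", "phosphorylation", 0), _eff("Rim15", "phosphorylation", 0)],
        HYPOTHETICAL,
        rule_class="gap_filler",
    ),
    _rule(
        "gf3_Xxx3",
        "Miscl",
        And(G0, present("Xxx3")),
        [_eff("Reg1", "phosphorylation", 0)],
        HYPOTHETICAL,
        rule_class="gap_filler",
    ),
    _rule(
        "gf4_Xxx4",
        "Miscl",
        And(G1, present("Xxx4")),
        [_eff("Msn2", "phosphorylation", 0), _eff("Msn4", "phosphorylation", 0)],
        HYPOTHETICAL,
        rule_class="gap_filler",
    ),
)

TOR_GAP_RULES = (
    _rule(
        "gf5_Xxx5",
        "Miscl",
        And(phos("Snf1", 0), present("Xxx5"), present("Kog1")),
        [_eff("Kog1", "phosphorylation", 0)],
        HYPOTHETICAL,
        rule_class="gap_filler",
    ),
    _rule(
        "gf6_Xxx6",
        "Miscl",
        And(phos("Snf1", 0), present("Xxx6"), present("Par32")),
        [_eff("Par32", "phosphorylation", 0)],
        HYPOTHETICAL,
        rule_class="gap_filler",
    ),
)


# ---------------------------------------------------------------------------
# crosstalk registry


def _ct_rule(rid, pathway, condition, effects, citation, ct_id):
    return _rule(rid, pathway, condition, effects, citation, rule_class="crosstalk", crosstalk_id=ct_id)


def _glucose_crosstalk() -> dict:
    reg = {}
    reg[1] = CrosstalkEntry(
        id=1,
        components=("Snf1", "Mth1", "Std1"),
        description="Active Snf1 prevents inactivation of Mth1 and Std1: "
        "with the crosstalk on, corepressor inactivation is gated by Snf1 "
        "activity instead of the membrane sensors.",
        citation="16487629;17369440",
        rules=(
            _ct_rule(
                "ct1a",
                "R2S3pw",
                And(present("Snf1"), phos("Snf1", 0), present("Grr1")),
                [_eff("Mth1", "phosphorylation", 1)],
                "16487629",
                1,
            ),
            _ct_rule(
                "ct1b",
                "R2S3pw",
                And(present("Snf1"), phos("Snf1", 0), present("Grr1")),
                [_eff("Std1", "phosphorylation", 1)],
                "16487629",
                1,
            ),
        ),
    )
    reg[2] = CrosstalkEntry(
        id=2,
        components=("Snf1", "Std1"),
        description="Std1 stimulates the Snf1 kinase activity.",
        citation="8078488;12455693",
        rules=(
            _ct_rule(
                "ct2",
                "Snf1pw",
                And(G0, present("Std1"), phos("Std1", 0), present("Sak1"), phos("Sak1", 0), present("Snf1")),
                [_eff("Snf1", "phosphorylation", 1)],
                "8078488",
                2,
            ),
        ),
    )
    reg[3] = CrosstalkEntry(
        id=3,
        components=("Reg1", "Glc7", "Yck1", "Yck2"),
        description="Reg1-Glc7 acts as an upstream activator of Yck1 and Yck2.",
        citation="16487629",
        rules=(
            _ct_rule(
                "ct3a",
                "R2S3pw",
                And(G1, present("Reg1"), phos("Reg1"), present("Glc7")),
                [_eff("Yck1", "phosphorylation", 1)],
                "16487629",
                3,
            ),
            _ct_rule(
                "ct3b",
                "R2S3pw",
                And(G1, present("Reg1"), phos("Reg1"), present("Glc7")),
                [_eff("Yck2", "phosphorylation", 1)],
                "16487629",
                3,
            ),
        ),
    )
    reg[4] = CrosstalkEntry(
        id=4,
        components=("PKA", "Sak1"),
        description="PKA complex phosphorylates Sak1 (inhibitory).",
        citation="22253824",
        rules=(
            _ct_rule("ct4a", "Snf1pw", And(active("PKA"), present("Sak1")), [_eff("Sak1", "phosphorylation", 1)], "22253824", 4),
            _ct_rule("ct4b", "Snf1pw", And(active("PKA", 0), present("Sak1")), [_eff("Sak1", "phosphorylation", 0)], "22253824", 4),
        ),
    )
    reg[5] = CrosstalkEntry(
        id=5,
        components=("Snf1", "PKA"),
        description="PKA complex negatively regulates the Snf1 pathway (Sak1 independent).",
        citation="22253824",
        rules=(
            _ct_rule("ct5", "Snf1pw", And(active("PKA"), present("Snf1")), [_eff("Snf1", "phosphorylation", 0)], "22253824", 5),
        ),
    )
    reg[6] = CrosstalkEntry(
        id=6,
        components=("Snf1", "Msn2"),
        description="Snf1 can phosphorylate Msn2 (activating site, glucose-depleted context).",
        citation="16247464",
        rules=(
            _ct_rule(
                "ct6",
                "PKApw",
                And(G0, present("Snf1"), phos("Snf1"), present("Msn2")),
                [_eff("Msn2", "phosphorylation", 1)],
                "16247464",
                6,
            ),
        ),
    )
    reg[7] = CrosstalkEntry(
        id=7,
        components=("PKA", "Glc7", "Reg1"),
        description="Glucose activation of the PKA pathway is required for "
        "activation of PP1 (Glc7-Reg1).",
        citation="22806045",
        wt_required=True,
        sweepable=False,
        rules=(
            _ct_rule("ct7", "Snf1pw", And(G1, present("Glc7"), present("Reg1")), [_eff("Reg1", "phosphorylation", 1)], "22806045", 7),
        ),
    )
    reg[8] = CrosstalkEntry(
        id=8,
        components=("Snf1", "Cyr1"),
        description="Snf1 deactivates Cyr1 by phosphorylation.",
        citation="26309184",
        rules=(
            _ct_rule(
                "ct8a",
                "PKApw",
                And(G0, present("Snf1"), phos("Snf1"), present("Cyr1")),
                [_eff("Cyr1", "phosphorylation", 1)],
                "26309184",
                8,
            ),
            _ct_rule(
                "ct8b",
                "PKApw",
                And(Or(G1, phos("Snf1", 0)), present("Cyr1")),
                [_eff("Cyr1", "phosphorylation", 0)],
                "26309184",
                8,
            ),
        ),
    )
    reg[9] = CrosstalkEntry(
        id=9,
        components=("PKA", "Rgt1"),
        description="Bcy1/PKA-dependent phosphorylation of Rgt1 under high glucose.",
        citation="16847060;21464310",
        wt_required=True,
        sweepable=False,
        rules=(
            _ct_rule(
                "ct9",
                "R2S3pw",
                And(G1, phos("Mth1"), phos("Std1"), present("Rgt1")),
                [_eff("Rgt1", "phosphorylation", 1)],
                "16847060",
                9,
            ),
        ),
    )
    return reg


def _tor_crosstalk() -> dict:
    reg = {}
    reg[10] = CrosstalkEntry(
        id=10,
        components=("Sch9", "Rim15"),
        description="Sch9 phosphorylates Rim15 (nitrogen input converging on Rim15).",
        citation="17308034",
        sweepable=False,
        rules=(
            _ct_rule(
                "ct10",
                "TORpw",
                And(G1, N1, present("Sch9"), phos("Sch9"), present("Rim15")),
                [_eff("Rim15", "phosphorylation", 1)],
                "17308034",
                10,
            ),
        ),
    )
    reg[11] = CrosstalkEntry(
        id=11,
        components=("TORC1", "Rim15"),
        description="TORC1 promotes Rim15 inhibition (converging on Rim15).",
        citation="14690591",
        sweepable=False,
        rules=(
            _ct_rule(
                "ct11",
                "TORpw",
                And(G1, N1, active("TORC1"), present("Rim15")),
                [_eff("Rim15", "phosphorylation", 1)],
                "14690591",
                11,
            ),
        ),
    )
    reg[12] = CrosstalkEntry(
        id=12,
        components=("Snf1", "Par32"),
        description="Active Snf1 phosphorylates the TORC1 effector Par32.",
        citation="25085507",
        sweepable=False,
        rules=(
            _ct_rule(
                "ct12",
                "TORpw",
                And(G0, present("Snf1"), phos("Snf1"), present("Par32")),
                [_eff("Par32", "phosphorylation", 1)],
                "25085507",
                12,
            ),
        ),
    )
    reg[13] = CrosstalkEntry(
        id=13,
        components=("Snf1", "Gln3", "Kog1"),
        description="Snf1-dependent phosphorylation of Gln3 (treated "
        "equivalently to TOR-dependent phosphorylation) and of the TORC1 "
        "subunit Kog1; drives nuclear Gln3 and NCR expression under glucose "
        "limitation even in nitrogen-rich conditions.",
        citation="19015258;25085507",
        sweepable=False,
        rules=(
            _ct_rule(
                "ct13a",
                "TORpw",
                And(G0, present("Snf1"), phos("Snf1"), present("Gln3")),
                [_eff("Gln3", "phosphorylation", 1)],
                "19015258",
                13,
            ),
            _ct_rule(
                "ct13b",
                "TORpw",
                And(G0, present("Snf1"), phos("Snf1"), present("Kog1")),
                [_eff("Kog1", "phosphorylation", 1)],
                "25085507",
                13,
            ),
        ),
    )
    return reg


# ---------------------------------------------------------------------------
# TOR base rule table (10 rules)

TOR_RULES = (
    _rule(
        "t01",
        "TORpw",
        And(N1, present("Tor1"), present("Kog1"), phos("Kog1", 0), present("Lst8"), present("Tco89")),
        [_eff("TORC1", "active", 1)],
        "12408816",
    ),
    _rule("t02", "TORpw", Or(N0, phos("Kog1")), [_eff("TORC1", "active", 0)], "12408816"),
    _rule("t03", "TORpw", And(active("TORC1"), present("Sch9")), [_eff("Sch9", "phosphorylation", 1)], "17560372"),
    _rule("t04", "TORpw", And(active("TORC1", 0), present("Sch9")), [_eff("Sch9", "phosphorylation", 0)], "17560372"),
    _rule("t05", "TORpw", And(active("TORC1"), present("Tap42")), [_eff("Tap42", "phosphorylation", 1)], "11741537"),
    _rule("t06", "TORpw", And(active("TORC1", 0), present("Tap42")), [_eff("Tap42", "phosphorylation", 0)], "11741537"),
    _rule(
        "t07",
        "TORpw",
        And(active("TORC1"), present("Ure2"), present("Gln3")),
        [_eff("Gln3", "phosphorylation", 1)],
        "10490601",
    ),
    _rule(
        "t08",
        "TORpw",
        And(active("TORC1"), present("Ure2"), present("Gln3")),
        [_eff("Gln3", "localization", "cytosol"), _eff("Gln3", "dna_bound", 0)],
        "10490601",
    ),
    _rule(
        "t09",
        "TORpw",
        And(
            N0,
            phos("Tap42", 0),
            present("Sit4"),
            present("Tpd3"),
            Or(present("Pph21"), present("Pph22")),
            phos("Snf1", 0),
            present("Gln3"),
        ),
        [_eff("Gln3", "phosphorylation", 0)],
        "10490601",
    ),
    _rule(
        "t10",
        "TORpw",
        And(active("TORC1", 0), present("Gln3")),
        [_eff("Gln3", "localization", "nucleus"), _eff("Gln3", "dna_bound", 1)],
        "10490601",
    ),
)


# ---------------------------------------------------------------------------
# gene map


@dataclass(frozen=True)
class GeneSpec:
    """One target gene: its group and the regulator condition that must
    hold at the LSS for the gene to be ON."""

    name: str
    group: str
    condition: Condition


def _suc2_condition() -> Condition:
    return Not(
        And(located("Mig1", "nucleus"), Atom("Mig1", "dna_bound", 1), present("Ssn6"), present("Tup1"))
    )


def _hxt_condition() -> Condition:
    # Rgt1 represses with Ssn6-Tup1 unless hyper-phosphorylated.
    return Not(
        And(
            present("Rgt1"),
            phos("Rgt1", 0),
            Atom("Rgt1", "dna_bound", 1),
            present("Ssn6"),
            present("Tup1"),
        )
    )


def _stre_condition() -> Condition:
    return Or(
        And(present("Msn2"), phos("Msn2"), located("Msn2", "nucleus")),
        And(present("Msn4"), phos("Msn4"), located("Msn4", "nucleus")),
    )


def _pds_condition() -> Condition:
    return And(present("Gis1"), phos("Gis1"))


def _ncr_condition() -> Condition:
    return And(present("Gln3"), located("Gln3", "nucleus"), Atom("Gln3", "dna_bound", 1))


GENE_GROUPS_GLUCOSE = {
    "SUC": ("SUC2",),
    "HXT": ("HXT1", "HXT2", "HXT3", "HXT4"),
    "HXK": ("HXK2",),
    "STRE": ("LSC1", "PDC6", "PDC5"),
    "PDS": ("RHR2", "HSP12", "DDR2", "CCT1"),
}

NCR_GENES = ("GAP1", "MEP2", "DAL5", "PUT1", "GDH2", "CAN1")

GENE_GROUPS_FULL = {**GENE_GROUPS_GLUCOSE, "NCR": NCR_GENES}

GROUP_ORDER_GLUCOSE = ("SUC", "HXT", "HXK", "STRE", "PDS")
GROUP_ORDER_FULL = GROUP_ORDER_GLUCOSE + ("NCR",)

_GROUP_CONDITIONS = {
    "SUC": _suc2_condition,
    "HXT": _hxt_condition,
    "HXK": _hxt_condition,  # HXK2 is Rgt1-regulated like the transporter genes
    "STRE": _stre_condition,
    "PDS": _pds_condition,
    "NCR": _ncr_condition,
}


def _gene_map(groups: Mapping[str, tuple]) -> tuple:
    specs = []
    for group, genes in groups.items():
        for gene in genes:
            specs.append(GeneSpec(gene, group, _GROUP_CONDITIONS[group]()))
    return tuple(specs)


# ---------------------------------------------------------------------------
# model builders


def build_glucose_model(
    include_gap_fillers: bool = True,
    crosstalk_flags: Optional[Mapping[int, int]] = None,
) -> ModelDefinition:
    """The glucose-signaling network (Snf3/Rgt2 + Snf1 + cAMP-PKA).

    The base rule table has exactly 61 literature-curated rules.  With
    ``include_gap_fillers`` the four hypothetical phosphatases Xxx1-Xxx4
    and their four rules are added; together with crosstalk reactions 7
    and 9 these are the six gap-filling conditions required for correct
    switching between nutrient conditions.
    """
    components = list(METABOLITES_GLUCOSE)
    components += list(R2S3_PROTEINS) + list(SNF1_PROTEINS) + list(PKA_PROTEINS)
    components.append(PKA_COMPLEX)
    components += list(MISC_PROTEINS)
    rules = list(_base_glucose_rules())
    if include_gap_fillers:
        components += list(GLUCOSE_GAP_COMPONENTS)
        rules += list(GLUCOSE_GAP_RULES)
    definition = ModelDefinition(
        name="glucose",
        pathways=PATHWAYS_GLUCOSE,
        components=tuple(components),
        rules=tuple(rules),
        crosstalk=_glucose_crosstalk(),
        gene_map=_gene_map(GENE_GROUPS_GLUCOSE),
        inputs={"Glucose": "glucose"},
    )
    definition.validate()
    if crosstalk_flags:
        definition = configure_model(definition, crosstalk_flags=crosstalk_flags)
    return definition


def build_full_model(crosstalk_flags: Optional[Mapping[int, int]] = None) -> ModelDefinition:
    """Glucose model plus the nitrogen-sensing TOR pathway.

    Adds the 15-protein TOR pathway (12 new proteins; Sch9, Rim15 and
    Snf1 are shared with the glucose rosters), TORC1 as the second
    complex component, nitrogen as the fourth metabolite, 10 TOR rules,
    the two TOR gap fillers Xxx5/Xxx6 (Kog1 and Par32 dephosphorylation)
    and four crosstalk reactions converging on Rim15 and Gln3.
    """
    components = list(METABOLITES_GLUCOSE) + [NITROGEN]
    components += list(R2S3_PROTEINS) + list(SNF1_PROTEINS) + list(PKA_PROTEINS)
    components.append(PKA_COMPLEX)
    components += list(TOR_PROTEINS_NEW)
    components.append(TORC1_COMPLEX)
    components += list(MISC_PROTEINS)
    components += list(GLUCOSE_GAP_COMPONENTS) + list(TOR_GAP_COMPONENTS)
    rules = (
        list(_base_glucose_rules())
        + list(TOR_RULES)
        + list(GLUCOSE_GAP_RULES)
        + list(TOR_GAP_RULES)
    )
    crosstalk = {**_glucose_crosstalk(), **_tor_crosstalk()}
    definition = ModelDefinition(
        name="full",
        pathways=PATHWAYS_FULL,
        components=tuple(components),
        rules=tuple(rules),
        crosstalk=crosstalk,
        gene_map=_gene_map(GENE_GROUPS_FULL),
        inputs={"Glucose": "glucose", "Nitrogen": "nitrogen"},
    )
    definition.validate()
    if crosstalk_flags:
        definition = configure_model(definition, crosstalk_flags=crosstalk_flags)
    return definition


WT_CROSSTALK_FLAGS = {7: 1, 9: 1}


def build_wt_model(model: str = "glucose", **kwargs) -> ModelDefinition:
    """The wild-type model: gap fillers plus the WT-required crosstalk
    reactions 7 (PKA-dependent PP1 activation) and 9 (PKA-dependent Rgt1
    phosphorylation); all sweepable crosstalks off."""
    if model == "glucose":
        return build_glucose_model(include_gap_fillers=True, crosstalk_flags=dict(WT_CROSSTALK_FLAGS), **kwargs)
    if model == "full":
        return build_full_model(crosstalk_flags=dict(WT_CROSSTALK_FLAGS), **kwargs)
    raise ConfigurationError(f"unknown model {model!r} (expected 'glucose' or 'full')")


# ---------------------------------------------------------------------------
# census


def model_census(definition: ModelDefinition) -> dict:
    """Count components, rules and registry entries of a definition.

    Complex-formation components are tallied separately and not included
    in the component total, matching the roster convention.
    """
    proteins = [c for c in definition.components if c.kind == "protein"]
    unknowns = [c for c in proteins if c.is_unknown]
    metabolites = [c for c in definition.components if c.kind == "metabolite"]
    complexes = [c for c in definition.components if c.kind == "complex"]
    base_rules = [r for r in definition.rules if r.rule_class == "base"]
    gap_rules = [r for r in definition.rules if r.rule_class == "gap_filler"]
    glucose_gap_rules = [r for r in gap_rules if r.id.startswith(("gf1", "gf2", "gf3", "gf4"))]
    wt_required_rules = [
        r for e in definition.crosstalk.values() if e.wt_required for r in e.rules
    ]
    tor_rules = [r for r in base_rules if r.pathway == "TORpw"]
    tor_proteins = [
        c.name for c in proteins if c.pathway == "TORpw" and not c.is_unknown
    ] + [n for n in TOR_SHARED_PROTEINS if n in definition.component_index]
    return {
        "components": len(proteins) + len(metabolites),
        "proteins": len(proteins),
        "known_proteins": len(proteins) - len(unknowns),
        "unknown_components": len(unknowns),
        "metabolites": len(metabolites),
        "complexes": len(complexes),
        "base_rules": len(base_rules),
        "glucose_base_rules": len(base_rules) - len(tor_rules),
        "tor_rules": len(tor_rules),
        "tor_pathway_proteins": len(tor_proteins) if tor_rules else 0,
        "gap_filler_rules": len(gap_rules),
        "gap_conditions": len(glucose_gap_rules) + len(wt_required_rules),
        "crosstalk_entries": len(definition.crosstalk),
        "target_genes": len(definition.gene_map),
    }


# ---------------------------------------------------------------------------
# gene readout


@dataclass(frozen=True)
class GeneExpressionPattern:
    """ON/OFF status of the target genes at a logical steady state."""

    genes: Mapping[str, int]
    group_of: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "genes", dict(self.genes))
        object.__setattr__(self, "group_of", dict(self.group_of))

    def groups(self) -> dict:
        """Group status: the shared value of the member genes.

        Raises ModelConsistencyError if members of one group disagree
        (impossible for the packaged models)."""
        out: dict = {}
        for gene, status in self.genes.items():
            group = self.group_of[gene]
            if group in out and out[group] != status:
                raise ModelConsistencyError(
                    f"genes of group {group!r} disagree at this steady state"
                )
            out[group] = status
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneExpressionPattern):
            return NotImplemented
        return self.genes == other.genes


def gene_status(lss: ModelState, gene_map: Optional[tuple] = None) -> GeneExpressionPattern:
    """Evaluate each gene's regulator condition at the LSS."""
    gene_map = gene_map if gene_map is not None else lss.definition.gene_map
    genes = {}
    group_of = {}
    for spec in gene_map:
        genes[spec.name] = int(spec.condition.evaluate(lss))
        group_of[spec.name] = spec.group
    return GeneExpressionPattern(genes, group_of)


def group_pattern(lss: ModelState, gene_map: Optional[tuple] = None) -> dict:
    """Convenience: gene-group ON/OFF map at the LSS."""
    return gene_status(lss, gene_map).groups()


# ---------------------------------------------------------------------------
# reference (expected) patterns

WT = "WT"
SNF1_KO = "snf1Δ"
RGT2_SNF3_KO = "rgt2Δsnf3Δ"
TPK_BCY1_KO = "tpk1Δtpk2Δtpk3Δbcy1Δ"

PERTURBATION_KNOCKOUTS = {
    WT: frozenset(),
    SNF1_KO: frozenset({"Snf1"}),
    RGT2_SNF3_KO: frozenset({"Rgt2", "Snf3"}),
    TPK_BCY1_KO: frozenset({"Tpk1", "Tpk2", "Tpk3", "Bcy1"}),
}

# expected group patterns (SUC, HXT, HXK, STRE, PDS) per glucose condition
_EXPECTED_WT = {
    1: {"SUC": 0, "HXT": 1, "HXK": 1, "STRE": 0, "PDS": 0},
    0: {"SUC": 1, "HXT": 0, "HXK": 0, "STRE": 1, "PDS": 1},
}

_EXPECTED_DEVIATIONS = {
    WT: {},
    SNF1_KO: {0: {"SUC": 0}},
    RGT2_SNF3_KO: {1: {"HXT": 0, "HXK": 0}},
    TPK_BCY1_KO: {1: {"PDS": 1}},
}

# expected NCR status per (glucose, nitrogen); the glucose-limitation row
# requires the Snf1-to-Gln3 crosstalk (id 13)
EXPECTED_NCR = {
    (1, 1): 0,
    (1, 0): 1,
    (0, 0): 1,
    (0, 1): 1,
}


def expected_pattern(condition: InputCondition, perturbation: str = WT) -> dict:
    """Reference gene-group pattern for a perturbation at a condition.

    These are the published expectation patterns used as the oracle for
    the simulation output (glucose-model groups only)."""
    if perturbation not in _EXPECTED_DEVIATIONS:
        raise ConfigurationError(
            f"unknown perturbation {perturbation!r}; expected one of "
            f"{sorted(_EXPECTED_DEVIATIONS)}"
        )
    pattern = dict(_EXPECTED_WT[condition.glucose])
    pattern.update(_EXPECTED_DEVIATIONS[perturbation].get(condition.glucose, {}))
    return pattern


# ---------------------------------------------------------------------------
# convenience prediction helpers


def predict_groups(
    definition: ModelDefinition,
    condition: InputCondition,
    knockouts=(),
    crosstalk_flags: Optional[Mapping[int, int]] = None,
) -> dict:
    """Group pattern after opposite-condition pre-equilibration."""
    configured = configure_model(
        definition,
        knockouts=frozenset(definition.knockouts) | frozenset(knockouts),
        crosstalk_flags={**definition.crosstalk_flags, **(crosstalk_flags or {})},
    )
    return group_pattern(predict(configured, condition))
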