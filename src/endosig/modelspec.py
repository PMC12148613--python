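"""Declarative definition of the default endothelial signaling network.

The mechanism set realises, at a coarse-grained granularity, the full
topology of the coupled pathways:

* VEGF axis: VEGF binding to VEGFR2, dimerisation and autophosphorylation;
  VEGFR1 as a decoy and as an R1-R2 heterodimer partner; NRP1 binding VEGF,
  VEGFR1 and active VEGFR2; TSP1/CD47 complexes blocking VEGFR2
  dimerisation; receptor internalisation / recycling / synthesis /
  degradation, with a dedicated degradation route for NRP1-associated
  internalised active receptor.
* Tie axis: tetrameric Ang1 seeds Tie2 clusters that grow one receptor at
  a time to the lumped size of four; only full clusters phosphorylate.
  Ang2 dimers/trimers occupy Tie2 without clustering; the Ang2 tetramer is
  a weak agonist (slower cluster formation).  Tie1-Tie2 heterodimers block
  ligand access at the surface; at the junction, heterodimer abundance
  slows VE-PTP dephosphorylation (stabilising gate).  Phospho-clusters
  translocate first-order to the junctional compartment, where VE-PTP
  dephosphorylates them and the cluster disassembles.  Tie1/Tie2 shed
  constitutively; soluble Tie2 traps Ang1 and Ang2 tetramer.
* Crosstalk: active VEGFR2 multiplies Tie2 shedding through a saturating
  enhancement term; VEGFR2 drives S1P production, which releases the
  finite WPB-stored Ang2 pool into the extracellular dimer/trimer/tetramer
  mixture; junctional pTie2 activates PI3K (Src-independent) and RhoA;
  RhoA-GTP binds mDia, and the complex sequesters free Src; pSrc
  phosphorylates VE-cadherin.
* Downstream: VEGFR2 activates Src and (in parallel) Axl; Src, Axl and
  junctional pTie2 converge on PI3K, which converts PIP2 to PIP3 to drive
  Akt; PLCgamma docks on active VEGFR2 and, once active, hydrolyses the
  shared PIP2 pool into DAG + IP3 (this competition for PIP2 couples
  PLCgamma abundance and turnover to Akt output); IP3 gates ER Ca release
  against a SERCA-style reuptake and a passive leak; DAG feeds Raf with a
  joint S1P-and-Ca requirement, then a linear Raf/MEK/Erk cascade; ppAkt
  with Ca activates eNOS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import Gate, ModelError, NetworkModel, ReactionRule, SpeciesDef

SUBSYSTEMS = ("vegf", "tie", "crosstalk", "downstream")


@dataclass(frozen=True)
class ModelConfig:
    """Which sub-modules to include, plus dosing conventions."""

    subsystems: frozenset = frozenset(SUBSYSTEMS)
    ang2_mixture: tuple = (("dim", 0.4), ("tri", 0.3), ("tet", 0.3))

    def __post_init__(self):
        bad = set(self.subsystems) - set(SUBSYSTEMS)
        if bad:
            raise ModelError(f"unknown sub-module name(s): {sorted(bad)}")


def _sp(name, comp, composition, init=None):
    return SpeciesDef(name, comp, composition, initial_value_key=init)


def _species_table():
    E, S, J, C, ER, I, W = (
        "extracellular", "surface", "junctional", "cytosol", "ER",
        "internalized", "WPB",
    )
    return [
        # extracellular ligands and shed ectodomains
        _sp("VEGF", E, {"VEGF": 1}),
        _sp("Ang1", E, {"Ang1": 4}),
        _sp("Ang2_dim", E, {"Ang2": 2}),
        _sp("Ang2_tri", E, {"Ang2": 3}),
        _sp("Ang2_tet", E, {"Ang2": 4}),
        _sp("TSP1", E, {"TSP1": 1}, "TSP1_0"),
        _sp("sTie2", E, {"Tie2": 1}),
        _sp("sTie1", E, {"Tie1": 1}),
        _sp("sTie2_Ang1", E, {"Tie2": 1, "Ang1": 4}),
        _sp("sTie2_Ang2", E, {"Tie2": 1, "Ang2": 4}),
        # VEGF-axis surface species
        _sp("VEGFR2", S, {"R2": 1}, "VEGFR2_0"),
        _sp("VEGFR1", S, {"R1": 1}, "VEGFR1_0"),
        _sp("NRP1", S, {"NRP1": 1}, "NRP1_0"),
        _sp("CD47", S, {"CD47": 1}, "CD47_0"),
        _sp("TSP1_CD47", S, {"TSP1": 1, "CD47": 1}),
        _sp("TSP1_CD47_VEGFR2", S, {"TSP1": 1, "CD47": 1, "R2": 1}),
        _sp("VEGF_VEGFR2", S, {"VEGF": 1, "R2": 1}),
        _sp("VEGF_VEGFR2_VEGFR2", S, {"VEGF": 1, "R2": 2}),
        _sp("pVEGFR2d", S, {"VEGF": 1, "R2": 2}),
        _sp("pVEGFR2d_NRP1", S, {"VEGF": 1, "R2": 2, "NRP1": 1}),
        _sp("pVEGFR2d_PLCg", S, {"VEGF": 1, "R2": 2, "PLCg": 1}),
        _sp("VEGF_VEGFR1", S, {"VEGF": 1, "R1": 1}),
        _sp("VEGFR1_VEGFR2", S, {"R1": 1, "R2": 1}),
        _sp("VEGF_NRP1", S, {"VEGF": 1, "NRP1": 1}),
        _sp("NRP1_VEGFR1", S, {"NRP1": 1, "R1": 1}),
        # Tie-axis surface species
        _sp("Tie2", S, {"Tie2": 1}, "Tie2_0"),
        _sp("Tie1", S, {"Tie1": 1}, "Tie1_0"),
        _sp("Tie1_Tie2", S, {"Tie1": 1, "Tie2": 1}),
        _sp("Ang1_Tie2", S, {"Ang1": 4, "Tie2": 1}),
        _sp("Ang1_Tie2_2", S, {"Ang1": 4, "Tie2": 2}),
        _sp("Ang1_Tie2_3", S, {"Ang1": 4, "Tie2": 3}),
        _sp("Ang1_Tie2_4", S, {"Ang1": 4, "Tie2": 4}),
        _sp("pTie2_s", S, {"Ang1": 4, "Tie2": 4}),
        _sp("Ang2_Tie2", S, {"Ang2": 4, "Tie2": 1}),
        _sp("Ang2_Tie2_4", S, {"Ang2": 4, "Tie2": 4}),
        _sp("pTie2_s_A2", S, {"Ang2": 4, "Tie2": 4}),
        _sp("Ang2d_Tie2", S, {"Ang2": 2, "Tie2": 1}),
        _sp("Ang2t_Tie2", S, {"Ang2": 3, "Tie2": 1}),
        # junctional compartment
        _sp("pTie2_j", J, {"Ang1": 4, "Tie2": 4}),
        _sp("pTie2_j_A2", J, {"Ang2": 4, "Tie2": 4}),
        _sp("VEPTP", J, {"VEPTP": 1}, "VEPTP_0"),
        # internalised VEGFR2 pools
        _sp("VEGFR2_i", I, {"R2": 1}),
        _sp("pVEGFR2d_i", I, {"VEGF": 1, "R2": 2}),
        _sp("pVEGFR2d_NRP1_i", I, {"VEGF": 1, "R2": 2, "NRP1": 1}),
        # cytosolic signaling
        _sp("Src", C, {"Src": 1}, "Src_0"),
        _sp("pSrc", C, {"Src": 1}),
        _sp("Axl", C, {"Axl": 1}, "Axl_0"),
        _sp("pAxl", C, {"Axl": 1}),
        _sp("RhoA_GDP", C, {"RhoA": 1}, "RhoA_0"),
        _sp("RhoA_GTP", C, {"RhoA": 1}),
        _sp("mDia", C, {"mDia": 1}, "mDia_0"),
        _sp("RhoAGTP_mDia", C, {"RhoA": 1, "mDia": 1}),
        _sp("mDiaSrc", C, {"RhoA": 1, "mDia": 1, "Src": 1}),
        _sp("PI3K", C, {"PI3K": 1}, "PI3K_0"),
        _sp("PI3Ka", C, {"PI3K": 1}),
        _sp("PIP2", C, {"lipid": 1}, "PIP2_0"),
        _sp("PIP3", C, {"lipid": 1}),
        _sp("DAG", C, {"lipid": 1}),
        _sp("IP3", C, {}),
        _sp("Akt", C, {"Akt": 1}, "Akt_0"),
        _sp("ppAkt", C, {"Akt": 1}),
        _sp("PLCg", C, {"PLCg": 1}, "PLCgamma_0"),
        _sp("pPLCg", C, {"PLCg": 1}),
        _sp("S1P", C, {}),
        _sp("eNOS", C, {"eNOS": 1}, "eNOS_0"),
        _sp("peNOS", C, {"eNOS": 1}),
        _sp("Raf", C, {"Raf": 1}, "Raf_0"),
        _sp("aRaf", C, {"Raf": 1}),
        _sp("MEK", C, {"MEK": 1}, "MEK_0"),
        _sp("pMEK", C, {"MEK": 1}),
        _sp("Erk", C, {"Erk": 1}, "Erk_0"),
        _sp("pErk", C, {"Erk": 1}),
        _sp("VEcad", C, {"VEcad": 1}, "VEcad_0"),
        _sp("pVEcad", C, {"VEcad": 1}),
        _sp("Ca_cyto", C, {"Ca": 1}, "Ca_cyto_0"),
        _sp("Ca_ER", ER, {"Ca": 1}, "Ca_ER_0"),
        _sp("WPB_Ang2", W, {"Ang2": 12}, "WPB_0"),
    ]


def _R(name, reactants, products, law, k, subsystems, *, Km=None, mod=None,
       rev=None, gates=(), nc=False, stoich=None, inh=None):
    return ReactionRule(
        name=name,
        reactants=tuple(reactants),
        products=tuple(products),
        rate_law=law,
        rate_constant_key=k,
        km_key=Km,
        modifier=mod,
        reversible=rev is not None,
        reverse_key=rev,
        gates=tuple(gates),
        non_conserving=nc,
        stoich_override=stoich,
        subsystems=frozenset(subsystems),
        inhibitor_target=inh or (),
    )


def _rule_table():
    MA, MM, SH = "mass_action", "michaelis_menten", "saturating_hill"
    V, T, X, D = ("vegf",), ("tie",), ("vegf", "tie", "crosstalk"), ("vegf", "downstream")
    XD = ("vegf", "tie", "crosstalk", "downstream")
    rules = [
        # ----- VEGF axis ----------------------------------------------------
        _R("vegf_bind_r2", ["VEGF", "VEGFR2"], ["VEGF_VEGFR2"], MA,
           "konvegfvegfr2", V, rev="koffvegfr2"),
        _R("r2_dimerize", ["VEGF_VEGFR2", "VEGFR2"], ["VEGF_VEGFR2_VEGFR2"], MA,
           "kdimvegfr2", V, rev="kundimvegfr2"),
        _R("r2_autophos", ["VEGF_VEGFR2_VEGFR2"], ["pVEGFR2d"], MA,
           "kphosvegfr2", V, inh="VEGFR2"),
        _R("r2_dephos", ["pVEGFR2d"], ["VEGF_VEGFR2_VEGFR2"], MA,
           "kdephosvegfr2", V),
        _R("vegf_bind_r1", ["VEGF", "VEGFR1"], ["VEGF_VEGFR1"], MA,
           "konvegfvegfr1", V, rev="koffvegfvegfr1"),
        _R("r1_r2_heterodimer", ["VEGFR1", "VEGFR2"], ["VEGFR1_VEGFR2"], MA,
           "konr1r2", V, rev="koffr1r2"),
        _R("vegf_bind_nrp1", ["VEGF", "NRP1"], ["VEGF_NRP1"], MA,
           "konvegfnrp1", V, rev="koffvegfnrp1"),
        _R("nrp1_bind_r1", ["NRP1", "VEGFR1"], ["NRP1_VEGFR1"], MA,
           "konnrp1vegfr1", V, rev="koffnrp1vegfr1"),
        _R("tsp1_bind_cd47", ["TSP1", "CD47"], ["TSP1_CD47"], MA,
           "kontsp1cd47", V, rev="kofftsp1cd47"),
        _R("tsp1cd47_bind_r2", ["TSP1_CD47", "VEGFR2"], ["TSP1_CD47_VEGFR2"], MA,
           "koncd47vegfr2", V, rev="koffcd47vegfr2"),
        _R("pr2_bind_nrp1", ["pVEGFR2d", "NRP1"], ["pVEGFR2d_NRP1"], MA,
           "konpr2nrp1", V, rev="koffpr2nrp1"),
        _R("r2_synthesis", [], ["VEGFR2"], MA, "ksynvegfr2", V, nc=True),
        _R("r2_internalize", ["VEGFR2"], ["VEGFR2_i"], MA, "kintvegfr2", V),
        # ligand-bound monomer internalises at the basal rate; the ligand is
        # degraded in the endosome
        _R("vr2_internalize", ["VEGF_VEGFR2"], ["VEGFR2_i"], MA,
           "kintvegfr2", V, nc=True),
        _R("r2_recycle", ["VEGFR2_i"], ["VEGFR2"], MA, "krecvegfr2", V),
        _R("r2_degrade", ["VEGFR2_i"], [], MA, "kdegvegfr2", V, nc=True),
        _R("r2_degrade_surface", ["VEGFR2"], [], MA, "kdegvegfr2", V, nc=True),
        _R("dimer_internalize", ["VEGF_VEGFR2_VEGFR2"], ["VEGFR2_i", "VEGFR2_i"],
           MA, "kintvegfr2", V, nc=True),
        _R("pr2_internalize", ["pVEGFR2d"], ["pVEGFR2d_i"], MA, "kintpvegfr2", V),
        _R("pr2plcg_internalize", ["pVEGFR2d_PLCg"], ["pVEGFR2d_i", "PLCg"],
           MA, "kintpvegfr2", ("vegf", "downstream")),
        _R("pr2i_degrade", ["pVEGFR2d_i"], [], MA, "kdegpvegfr2", V, nc=True),
        _R("pr2nrp_internalize", ["pVEGFR2d_NRP1"], ["pVEGFR2d_NRP1_i"], MA,
           "kintpvegfr2nrp", V),
        _R("pr2nrpi_degrade", ["pVEGFR2d_NRP1_i"], [], MA,
           "kdegvegfr2dpe2_nrp", V, nc=True),
        # ----- Tie axis -----------------------------------------------------
        _R("tie1_bind_tie2", ["Tie1", "Tie2"], ["Tie1_Tie2"], MA,
           "kontie1tie2", T, rev="kofftie1tie2"),
        _R("ang1_seed", ["Ang1", "Tie2"], ["Ang1_Tie2"], MA,
           "konang1tie2", T, rev="koffang1tie2"),
        _R("ang1_clust2", ["Ang1_Tie2", "Tie2"], ["Ang1_Tie2_2"], MA,
           "kclusttie2", T, rev="kunclusttie2"),
        _R("ang1_clust3", ["Ang1_Tie2_2", "Tie2"], ["Ang1_Tie2_3"], MA,
           "kclusttie2", T, rev="kunclusttie2"),
        _R("ang1_clust4", ["Ang1_Tie2_3", "Tie2"], ["Ang1_Tie2_4"], MA,
           "kclusttie2", T, rev="kunclusttie2"),
        _R("tie2_phos", ["Ang1_Tie2_4"], ["pTie2_s"], MA, "kphostie2", T),
        _R("tie2_s_dephos", ["pTie2_s"], ["Ang1_Tie2_4"], MA, "kdephostie2s", T),
        _R("ang2tet_seed", ["Ang2_tet", "Tie2"], ["Ang2_Tie2"], MA,
           "konang2tie2", T, rev="koffang2tie2"),
        # lumped: the seeded Ang2 tetramer recruits its remaining three Tie2
        # in one step (rate bilinear in seed and Tie2, consuming 3 Tie2)
        _R("ang2_clust", ["Ang2_Tie2", "Tie2"], ["Ang2_Tie2_4"], MA,
           "kclustang2tie2", T,
           stoich={"Ang2_Tie2": -1, "Tie2": -3, "Ang2_Tie2_4": 1}),
        _R("ang2_unclust", ["Ang2_Tie2_4"], ["Ang2_Tie2", "Tie2"], MA,
           "kunclustang2tie2", T,
           stoich={"Ang2_Tie2_4": -1, "Ang2_Tie2": 1, "Tie2": 3}),
        _R("tie2_phos_a2", ["Ang2_Tie2_4"], ["pTie2_s_A2"], MA, "kphostie2", T),
        _R("tie2_s_dephos_a2", ["pTie2_s_A2"], ["Ang2_Tie2_4"], MA,
           "kdephostie2s", T),
        _R("ang2dim_bind", ["Ang2_dim", "Tie2"], ["Ang2d_Tie2"], MA,
           "konang2tie2", T, rev="koffang2tie2"),
        _R("ang2tri_bind", ["Ang2_tri", "Tie2"], ["Ang2t_Tie2"], MA,
           "konang2tie2", T, rev="koffang2tie2"),
        _R("tie2_to_junction", ["pTie2_s"], ["pTie2_j"], MA, "kjunctie2", T),
        _R("tie2_to_junction_a2", ["pTie2_s_A2"], ["pTie2_j_A2"], MA,
           "kjunctie2", T),
        # VE-PTP dephosphorylation disassembles the junctional cluster;
        # Tie1-Tie2 heterodimer abundance slows it (junctional stabilisation)
        _R("veptp_dephos", ["pTie2_j"], ["Ang1"] + ["Tie2"] * 4, MM,
           "kcatveptp", T, Km="Kmveptp", mod="VEPTP",
           gates=[Gate("Tie1_Tie2", "Kstabtie1", -1)]),
        _R("veptp_dephos_a2", ["pTie2_j_A2"], ["Ang2_tet"] + ["Tie2"] * 4, MM,
           "kcatveptp", T, Km="Kmveptp", mod="VEPTP",
           gates=[Gate("Tie1_Tie2", "Kstabtie1", -1)]),
        _R("ptie2j_degrade", ["pTie2_j"], [], MA, "kdegptie2", T, nc=True),
        _R("ptie2j_a2_degrade", ["pTie2_j_A2"], [], MA, "kdegptie2", T, nc=True),
        _R("tie2_synthesis", [], ["Tie2"], MA, "ksyntie2", T, nc=True),
        _R("tie2_degrade", ["Tie2"], [], MA, "kdegtie2", T, nc=True),
        _R("tie2_shed", ["Tie2"], ["sTie2"], MA, "kshedtie2", T),
        _R("tie1_shed", ["Tie1"], ["sTie1"], MA, "kshedtie1", T),
        # Tie1 shedding from the heterodimer liberates Tie2
        _R("tie1tie2_shed", ["Tie1_Tie2"], ["sTie1", "Tie2"], MA,
           "kshedtie1", T),
        _R("tie1tie2_degrade", ["Tie1_Tie2"], [], MA, "kdegtie1", T, nc=True),
        _R("tie1_synthesis", [], ["Tie1"], MA, "ksyntie1", T, nc=True),
        _R("tie1_degrade", ["Tie1"], [], MA, "kdegtie1", T, nc=True),
        _R("stie2_trap_ang1", ["sTie2", "Ang1"], ["sTie2_Ang1"], MA,
           "konstie2ang1", T, rev="koffstie2ang1"),
        _R("stie2_trap_ang2", ["sTie2", "Ang2_tet"], ["sTie2_Ang2"], MA,
           "konstie2ang2", T, rev="koffstie2ang2"),
        _R("stie2_clear", ["sTie2"], [], MA, "kclrstie2", T, nc=True),
        _R("stie1_clear", ["sTie1"], [], MA, "kclrstie1", T, nc=True),
        _R("stie2ang1_clear", ["sTie2_Ang1"], ["Ang1"], MA, "kclrstie2", T,
           nc=True),
        _R("stie2ang2_clear", ["sTie2_Ang2"], ["Ang2_tet"], MA, "kclrstie2", T,
           nc=True),
        # ----- crosstalk ----------------------------------------------------
        # VEGF-enhanced Tie2 shedding, saturating in active VEGFR2
        _R("tie2_shed_vegf", ["Tie2"], ["sTie2"], SH, "kshedvegftie2", X,
           Km="Kshedvegf", mod="pVEGFR2d", inh="VEGFR2"),
        _R("s1p_production", [], ["S1P"], SH, "ks1p", ("vegf", "crosstalk"),
           Km="Ks1pact", mod="pVEGFR2d", inh="VEGFR2"),
        _R("s1p_decay", ["S1P"], [], MA, "kdegs1p", ("vegf", "crosstalk")),
        # WPB exocytosis: each 12-monomer packet leaves as 6 dimers, 4
        # trimers or 3 tetramers; the three rates set the release mixture
        _R("wpb_release_dim", ["WPB_Ang2"], ["Ang2_dim"] * 6, SH,
           "krelwpb_dim", X, Km="KwpbS1P", mod="S1P"),
        _R("wpb_release_tri", ["WPB_Ang2"], ["Ang2_tri"] * 4, SH,
           "krelwpb_tri", X, Km="KwpbS1P", mod="S1P"),
        _R("wpb_release_tet", ["WPB_Ang2"], ["Ang2_tet"] * 3, SH,
           "krelwpb_tet", X, Km="KwpbS1P", mod="S1P"),
        # junctional pTie2 -> RhoA-GTP -> mDia -> Src sequestration
        _R("rhoa_activate", ["RhoA_GDP"], ["RhoA_GTP"], MM, "kactrhoa",
           ("tie", "crosstalk"), Km="KmrhoA", mod="pTie2_j"),
        _R("rhoa_activate_a2", ["RhoA_GDP"], ["RhoA_GTP"], MM, "kactrhoa",
           ("tie", "crosstalk"), Km="KmrhoA", mod="pTie2_j_A2"),
        _R("rhoa_hydrolyze", ["RhoA_GTP"], ["RhoA_GDP"], MA, "khydrhoa",
           ("tie", "crosstalk")),
        _R("rhoa_bind_mdia", ["RhoA_GTP", "mDia"], ["RhoAGTP_mDia"], MA,
           "konrhomdia", ("tie", "crosstalk"), rev="koffrhomdia"),
        _R("mdia_seq_src", ["RhoAGTP_mDia", "Src"], ["mDiaSrc"], MA,
           "konmdiasrc", ("tie", "crosstalk", "downstream"),
           rev="koffmdiasrc"),
        # Src-independent PI3K activation by junctional pTie2; saturating in
        # the cluster signal so the route contributes a bounded flux
        _R("pi3k_act_tie2", ["PI3K"], ["PI3Ka"], SH, "kactpi3ktie2",
           ("tie", "crosstalk", "downstream"), Km="Ktie2pi3k", mod="pTie2_j"),
        _R("pi3k_act_tie2_a2", ["PI3K"], ["PI3Ka"], SH, "kactpi3ktie2",
           ("tie", "crosstalk", "downstream"), Km="Ktie2pi3k",
           mod="pTie2_j_A2"),
        # ----- downstream ---------------------------------------------------
        _R("src_activate", ["Src"], ["pSrc"], MM, "kactivesrc", D,
           Km="KmSrc", mod="pVEGFR2d", inh=("Src", "VEGFR2")),
        _R("src_deactivate", ["pSrc"], ["Src"], MA, "kdeactsrc", D),
        _R("axl_activate", ["Axl"], ["pAxl"], MM, "kactiveaxl", D,
           Km="KmAxl", mod="pVEGFR2d", inh=("Axl", "VEGFR2")),
        _R("axl_deactivate", ["pAxl"], ["Axl"], MA, "kdeactaxl", D),
        _R("pi3k_act_src", ["PI3K"], ["PI3Ka"], MM, "kactpi3ksrc", D,
           Km="Kmpi3k", mod="pSrc"),
        _R("pi3k_act_axl", ["PI3K"], ["PI3Ka"], MM, "kactpi3kaxl", D,
           Km="Kmpi3k", mod="pAxl"),
        _R("pi3k_inactivate", ["PI3Ka"], ["PI3K"], MA, "kinactPI3K", D),
        _R("pip2_to_pip3", ["PIP2"], ["PIP3"], MM, "kcatpi3kpip2", D,
           Km="KmPIP2", mod="PI3Ka"),
        _R("pip3_to_pip2", ["PIP3"], ["PIP2"], MA, "kdeppip3", D),
        _R("akt_activate", ["Akt"], ["ppAkt"], MM, "kcatPI3KAkt", D,
           Km="KmAkt", mod="PIP3", inh="Akt"),
        _R("akt_deactivate", ["ppAkt"], ["Akt"], MA, "kdeactakt", D),
        _R("plcg_dock", ["pVEGFR2d", "PLCg"], ["pVEGFR2d_PLCg"], MA,
           "konplcg", D, rev="koffplcg"),
        _R("plcg_activate", ["pVEGFR2d_PLCg"], ["pVEGFR2d", "pPLCg"], MA,
           "kcatplcg", D, inh="VEGFR2"),
        _R("plcg_deactivate", ["pPLCg"], ["PLCg"], MA, "kdeactplcg", D),
        # PLCgamma hydrolyses PIP2 (shared with PI3K) into DAG + IP3
        _R("pip2_hydrolysis", ["PIP2"], ["DAG", "IP3"], MM,
           "kcatPLCgammaDAG", D, Km="KmPIP2plc", mod="pPLCg"),
        _R("dag_recycle", ["DAG"], ["PIP2"], MA, "krecdag", D),
        _R("ip3_decay", ["IP3"], [], MA, "kdegip3", D),
        # minimal three-flux calcium cycle
        _R("ca_release", ["Ca_ER"], ["Ca_cyto"], SH, "krelca", D,
           Km="KIP3ca", mod="IP3"),
        _R("ca_leak", ["Ca_ER"], ["Ca_cyto"], MA, "kleakca", D),
        _R("ca_serca", ["Ca_cyto"], ["Ca_ER"], MM, "vserca", D, Km="Kserca"),
        _R("enos_activate", ["eNOS"], ["peNOS"], MM, "kcatenos", D,
           Km="Kmenos", mod="ppAkt", gates=[Gate("Ca_cyto", "Kcaenos", 1)]),
        _R("enos_deactivate", ["peNOS"], ["eNOS"], MA, "kdeactenos", D),
        # DAG feeds Raf; S1P and Ca jointly required
        _R("raf_activate", ["Raf"], ["aRaf"], MM, "kactraf", D,
           Km="KmRaf", mod="DAG",
           gates=[Gate("S1P", "Ks1praf", 1), Gate("Ca_cyto", "Kcaraf", 1)]),
        _R("raf_deactivate", ["aRaf"], ["Raf"], MA, "kdeactraf", D),
        _R("mek_activate", ["MEK"], ["pMEK"], MM, "kcatmek", D,
           Km="KmMEK", mod="aRaf"),
        _R("mek_deactivate", ["pMEK"], ["MEK"], MA, "kdeactmek", D),
        _R("erk_activate", ["Erk"], ["pErk"], MM, "kcaterk", D,
           Km="KmErk", mod="pMEK"),
        _R("erk_deactivate", ["pErk"], ["Erk"], MA, "kdeacterk", D),
        _R("vecad_phos", ["VEcad"], ["pVEcad"], MM, "kphosvecad", D,
           Km="KmVEc", mod="pSrc"),
        _R("vecad_dephos", ["pVEcad"], ["VEcad"], MA, "kdephosvecad", D),
    ]
    # Ectodomain shedding cleaves Tie2 regardless of ligand occupancy: every
    # non-phosphorylated surface Tie2-containing state sheds one receptor at
    # the constitutive rate, with the same VEGF-driven enhancement as free
    # Tie2.  Junctional phospho-clusters are protected.
    shed_targets = [
        ("Tie1_Tie2", ["sTie2", "Tie1"]),
        ("Ang1_Tie2", ["sTie2", "Ang1"]),
        ("Ang1_Tie2_2", ["sTie2", "Ang1_Tie2"]),
        ("Ang1_Tie2_3", ["sTie2", "Ang1_Tie2_2"]),
        ("Ang1_Tie2_4", ["sTie2", "Ang1_Tie2_3"]),
        ("Ang2_Tie2", ["sTie2", "Ang2_tet"]),
        ("Ang2d_Tie2", ["sTie2", "Ang2_dim"]),
        ("Ang2t_Tie2", ["sTie2", "Ang2_tri"]),
    ]
    for src, products in shed_targets:
        rules.append(_R(f"shed_{src.lower()}", [src], products, MA,
                        "kshedtie2", T))
        rules.append(_R(f"shed_vegf_{src.lower()}", [src], products, SH,
                        "kshedvegftie2", X, Km="Kshedvegf", mod="pVEGFR2d",
                        inh="VEGFR2"))
    return rules


def _observable_table():
    active_r2 = ["pVEGFR2d", "pVEGFR2d_NRP1", "pVEGFR2d_PLCg",
                 "pVEGFR2d_i", "pVEGFR2d_NRP1_i"]
    surf_r2 = {
        "VEGFR2": 1, "VEGF_VEGFR2": 1, "VEGF_VEGFR2_VEGFR2": 2,
        "pVEGFR2d": 2, "pVEGFR2d_NRP1": 2, "pVEGFR2d_PLCg": 2,
        "VEGFR1_VEGFR2": 1, "TSP1_CD47_VEGFR2": 1,
    }
    total_r2 = dict(surf_r2)
    total_r2.update({"VEGFR2_i": 1, "pVEGFR2d_i": 2, "pVEGFR2d_NRP1_i": 2})
    ptie2_surface = {"pTie2_s": 4, "pTie2_s_A2": 4}
    ptie2_junctional = {"pTie2_j": 4, "pTie2_j_A2": 4}
    ptie2 = dict(ptie2_surface)
    ptie2.update(ptie2_junctional)
    return {
        "pVEGFR2": {s: 1 for s in active_r2},
        "surface_VEGFR2": surf_r2,
        "total_VEGFR2": total_r2,
        "pTie2": ptie2,
        "pTie2_surface": ptie2_surface,
        "pTie2_junctional": ptie2_junctional,
        "pSrc": {"pSrc": 1},
        "free_Src": {"Src": 1},
        "sequestered_Src": {"mDiaSrc": 1},
        "pAxl": {"pAxl": 1},
        "ppAkt": {"ppAkt": 1},
        "pErk": {"pErk": 1},
        "pPLCg": {"pPLCg": 1},
        "peNOS": {"peNOS": 1},
        "pVEcad": {"pVEcad": 1},
        "Ca_cyto": {"Ca_cyto": 1},
        "S1P": {"S1P": 1},
        "sTie2": {"sTie2": 1, "sTie2_Ang1": 1, "sTie2_Ang2": 1},
        "Ang2_extracellular": {"Ang2_dim": 2, "Ang2_tri": 3, "Ang2_tet": 4},
        "WPB_Ang2": {"WPB_Ang2": 12},
        "RhoA_GTP": {"RhoA_GTP": 1, "RhoAGTP_mDia": 1, "mDiaSrc": 1},
        "mDiaSrc_complex": {"mDiaSrc": 1},
    }


def build_default_model(config: ModelConfig | None = None) -> NetworkModel:
    """Assemble the default network, restricted to the configured
    sub-modules.

    A rule is included when every subsystem it touches is enabled; species
    not referenced by any included rule (and without an initial-value key
    relevant to an included subsystem) are dropped, so reduced models stay
    small and never carry dangling parameter keys.
    """
    config = config or ModelConfig()
    enabled = set(config.subsystems)
    rules = [r for r in _rule_table() if r.subsystems <= enabled]
    referenced = set()
    for r in rules:
        referenced.update(r.reactants)
        referenced.update(r.products)
        referenced.update(r.stoichiometry())
        if r.modifier:
            referenced.add(r.modifier)
        referenced.update(g.species for g in r.gates)
    species = [s for s in _species_table() if s.name in referenced]
    kept = {s.name for s in species}
    observables = {}
    for name, weights in _observable_table().items():
        w = {s: c for s, c in weights.items() if s in kept}
        if w:
            observables[name] = w
    model = NetworkModel(species=species, rules=rules,
                         observables=observables, config=config)
    bad = model.check_monomer_balance()
    if bad:  # pragma: no cover - construction-time sanity check
        raise ModelError(f"rules violate monomer balance: {bad}")
    return model
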