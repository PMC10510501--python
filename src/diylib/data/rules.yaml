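# Default main-reaction and side-reaction rule set.
#
# Main reactions: the four robust categories used for library enumeration
# (amide and ester bond formation with coupling agents; SNAr of
# electron-poor aryl halides and Buchwald-Hartwig amination; and the
# Pd-catalyzed C-C couplings Suzuki, Sonogashira and Heck).
#
# Each rule carries the SMARTS pattern of its two reagent roles, a SMIRKS
# transform producing one product from two reactants, the condition class
# that governs side-reaction gating, the molecular formula removed from the
# combined reactants (X stands for the halogen consumed), and a smoke-test
# reagent pair used to validate the transform at load time.
#
# Side patterns: substructures that predict byproducts under the listed
# condition classes and therefore veto a reagent pairing.  The set is an
# open, documented starting point and is meant to be extended per lab.

rules:
  amide:
    role_a: "[CX3](=[OX1])[OX2H1]"
    role_b: "[NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]);!$([NX3][NX3]);!$([NX3][OX2])]"
    transform: "[CX3:1](=[OX1:2])[OX2H1].[NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]);!$([NX3][NX3]);!$([NX3][OX2]):3]>>[C:1](=[O:2])[N:3]"
    condition_class: coupling_agent
    leaving_formula: H2O
    smoke: ["CC(=O)O", "CN"]
  ester:
    role_a: "[CX3](=[OX1])[OX2H1]"
    role_b: "[OX2H1;$([OX2H1][CX4]),$([OX2H1]c)]"
    transform: "[CX3:1](=[OX1:2])[OX2H1].[OX2H1;$([OX2H1][CX4]),$([OX2H1]c):3]>>[C:1](=[O:2])[O:3]"
    condition_class: coupling_agent
    leaving_formula: H2O
    smoke: ["CC(=O)O", "OCC"]
  snar:
    # halide on a six-membered azine ring, or ortho/para to a nitro group
    role_a: "[c;$(c1naaaa1),$(c1anaaa1),$(c1aanaa1),$(c1c([N+](=O)[O-])aaaa1),$(c1aac([N+](=O)[O-])aa1)][F,Cl,Br,I]"
    role_b: "[$([NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]);!$([NX3][NX3]);!$([NX3][OX2])]),$([OX2H1][CX4]),$([SX2H1])]"
    transform: "[c;$(c1naaaa1),$(c1anaaa1),$(c1aanaa1),$(c1c([N+](=O)[O-])aaaa1),$(c1aac([N+](=O)[O-])aa1):1][F,Cl,Br,I].[$([NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]);!$([NX3][NX3]);!$([NX3][OX2])]),$([OX2H1][CX4]),$([SX2H1]):2]>>[c:1][*:2]"
    condition_class: base_only
    leaving_formula: HX
    smoke: ["Clc1ccncc1", "CN"]
  buchwald:
    role_a: "c[Cl,Br,I]"
    role_b: "[NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]);!$([NX3][NX3]);!$([NX3][OX2])]"
    transform: "[c:1][Cl,Br,I].[NX3;H2,H1;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][SX4]);!$([NX3][NX3]);!$([NX3][OX2]):2]>>[c:1][N:2]"
    condition_class: pd_catalyst
    leaving_formula: HX
    smoke: ["Brc1ccccc1", "CN"]
  suzuki:
    role_a: "c[Cl,Br,I]"
    role_b: "[$([cX3]),$([CX3]=[CX3])][BX3]([OX2H1])[OX2H1]"
    transform: "[c:1][Cl,Br,I].[$([cX3]),$([CX3]=[CX3]):2][BX3]([OX2H1])[OX2H1]>>[c:1][*:2]"
    condition_class: pd_catalyst
    leaving_formula: H2BO2X
    smoke: ["Brc1ccccc1", "OB(O)c1ccccc1"]
  sonogashira:
    role_a: "c[Cl,Br,I]"
    role_b: "[CX2]#[CX2H1]"
    transform: "[c:1][Cl,Br,I].[CX2:2]#[CX2H1:3]>>[c:1][C:3]#[C:2]"
    condition_class: pd_catalyst
    leaving_formula: HX
    smoke: ["Brc1ccccc1", "C#CC"]
  heck:
    role_a: "c[Cl,Br,I]"
    role_b: "[CX3H2]=[CX3H1][#6]"
    transform: "[c:1][Cl,Br,I].[CX3H2:2]=[CX3H1:3][#6:4]>>[c:1]/[CH1:2]=[CH1:3]/[#6:4]"
    condition_class: pd_catalyst
    leaving_formula: HX
    smoke: ["Brc1ccccc1", "C=CC"]

side_patterns:
  aliphatic_halide:
    pattern: "[CX4][Cl,Br,I]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  acyl_halide:
    pattern: "[CX3](=[OX1])[F,Cl,Br,I]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  anhydride:
    pattern: "[CX3](=[OX1])[OX2][CX3](=[OX1])"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  sulfonyl_halide:
    pattern: "[SX4](=[OX1])(=[OX1])[F,Cl,Br]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  free_thiol:
    # main-reaction nucleophile under SNAr base conditions; poisons Pd and
    # competes with amide/ester activation elsewhere
    pattern: "[SX2H1]"
    blocks_under: [coupling_agent, pd_catalyst]
  aldehyde:
    pattern: "[CX3H1]=[OX1]"
    blocks_under: [pd_catalyst]
  nh_azole:
    pattern: "[nX3H1]"
    blocks_under: [base_only]
  labile_aryl_ester:
    pattern: "[CX3](=[OX1])[OX2]c"
    blocks_under: [coupling_agent, base_only]
  isocyanate:
    pattern: "[NX2]=[CX2]=[OX1]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  isothiocyanate:
    pattern: "[NX2]=[CX2]=[SX1]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  epoxide:
    pattern: "[OX2r3]1[#6r3][#6r3]1"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  aziridine:
    pattern: "[NX3r3]1[#6r3][#6r3]1"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  azide:
    pattern: "[NX2]=[NX2+]=[NX1-]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  diazonium:
    pattern: "[NX2+]#[NX1]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  peroxide:
    pattern: "[OX2][OX2]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  michael_acceptor:
    pattern: "[CX3]=[CX3][CX3]=[OX1]"
    blocks_under: [coupling_agent, base_only]
  vinyl_sulfone:
    pattern: "[CX3]=[CX3][SX4](=[OX1])=[OX1]"
    blocks_under: [coupling_agent, base_only]
  maleimide:
    pattern: "[CX3]1=[CX3][CX3](=[OX1])[NX3][CX3]1=[OX1]"
    blocks_under: [coupling_agent, base_only]
  alpha_halo_carbonyl:
    pattern: "[CX3](=[OX1])[CX4][Cl,Br,I]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  chloroformate:
    pattern: "[OX2][CX3](=[OX1])[Cl,Br]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
  hydrazine:
    pattern: "[NX3H2][NX3]"
    blocks_under: [coupling_agent]
  hydroxylamine:
    pattern: "[NX3][OX2H1]"
    blocks_under: [coupling_agent]
  imine:
    pattern: "[CX3]=[NX2][#6]"
    blocks_under: [coupling_agent]
  nitroso:
    pattern: "[NX2]=[OX1]"
    blocks_under: [coupling_agent, base_only, pd_catalyst]
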