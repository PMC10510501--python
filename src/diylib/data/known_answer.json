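{
 "step1_inchis": [
  "InChI=1S/C12H10/c1-3-7-11(8-4-1)12-9-5-2-6-10-12/h1-10H",
  "InChI=1S/C12H11N/c1-3-7-11(8-4-1)13-12-9-5-2-6-10-12/h1-10,13H",
  "InChI=1S/C13H11NO/c15-13(11-7-3-1-4-8-11)14-12-9-5-2-6-10-12/h1-10H,(H,14,15)",
  "InChI=1S/C13H13N/c1-3-7-12(8-4-1)11-14-13-9-5-2-6-10-13/h1-10,14H,11H2",
  "InChI=1S/C14H13NO/c16-14(13-9-5-2-6-10-13)15-11-12-7-3-1-4-8-12/h1-10H,11H2,(H,15,16)",
  "InChI=1S/C3H7NO/c1-3(5)4-2/h1-2H3,(H,4,5)",
  "InChI=1S/C4H10N2O/c1-4(7)6-3-2-5/h2-3,5H2,1H3,(H,6,7)",
  "InChI=1S/C7H9N/c1-8-7-5-3-2-4-6-7/h2-6,8H,1H3",
  "InChI=1S/C8H12N2/c9-6-7-10-8-4-2-1-3-5-8/h1-5,10H,6-7,9H2",
  "InChI=1S/C8H9NO/c1-7(10)9-8-5-3-2-4-6-8/h2-6H,1H3,(H,9,10)",
  "InChI=1S/C8H9NO/c1-9-8(10)7-5-3-2-4-6-7/h2-6H,1H3,(H,9,10)",
  "InChI=1S/C9H11NO/c1-8(11)10-7-9-5-3-2-4-6-9/h2-6H,7H2,1H3,(H,10,11)",
  "InChI=1S/C9H12N2O/c10-6-7-11-9(12)8-4-2-1-3-5-8/h1-5H,6-7,10H2,(H,11,12)"
 ],
 "step2_inchis": [
  "InChI=1S/C10H14N2O/c1-9(13)11-7-8-12-10-5-3-2-4-6-10/h2-6,12H,7-8H2,1H3,(H,11,13)",
  "InChI=1S/C10H14N2O/c1-9(13)12(8-7-11)10-5-3-2-4-6-10/h2-6H,7-8,11H2,1H3",
  "InChI=1S/C11H14N2O2/c1-9(14)12-7-8-13-11(15)10-5-3-2-4-6-10/h2-6H,7-8H2,1H3,(H,12,14)(H,13,15)",
  "InChI=1S/C13H13N/c1-14(12-8-4-2-5-9-12)13-10-6-3-7-11-13/h2-11H,1H3",
  "InChI=1S/C14H13NO/c1-12(16)15(13-8-4-2-5-9-13)14-10-6-3-7-11-14/h2-11H,1H3",
  "InChI=1S/C14H13NO/c1-15(13-10-6-3-7-11-13)14(16)12-8-4-2-5-9-12/h2-11H,1H3",
  "InChI=1S/C14H16N2/c1-3-7-13(8-4-1)15-11-12-16-14-9-5-2-6-10-14/h1-10,15-16H,11-12H2",
  "InChI=1S/C14H16N2/c15-11-12-16(13-7-3-1-4-8-13)14-9-5-2-6-10-14/h1-10H,11-12,15H2",
  "InChI=1S/C15H15NO/c1-13(17)16(15-10-6-3-7-11-15)12-14-8-4-2-5-9-14/h2-11H,12H2,1H3",
  "InChI=1S/C15H16N2O/c16-11-12-17(14-9-5-2-6-10-14)15(18)13-7-3-1-4-8-13/h1-10H,11-12,16H2",
  "InChI=1S/C15H16N2O/c18-15(13-7-3-1-4-8-13)17-12-11-16-14-9-5-2-6-10-14/h1-10,16H,11-12H2,(H,17,18)",
  "InChI=1S/C16H16N2O2/c19-15(13-7-3-1-4-8-13)17-11-12-18-16(20)14-9-5-2-6-10-14/h1-10H,11-12H2,(H,17,19)(H,18,20)",
  "InChI=1S/C18H15N/c1-4-10-16(11-5-1)19(17-12-6-2-7-13-17)18-14-8-3-9-15-18/h1-15H",
  "InChI=1S/C19H15NO/c21-19(16-10-4-1-5-11-16)20(17-12-6-2-7-13-17)18-14-8-3-9-15-18/h1-15H",
  "InChI=1S/C19H17N/c1-4-10-17(11-5-1)16-20(18-12-6-2-7-13-18)19-14-8-3-9-15-19/h1-15H,16H2",
  "InChI=1S/C20H17NO/c22-20(18-12-6-2-7-13-18)21(19-14-8-3-9-15-19)16-17-10-4-1-5-11-17/h1-15H,16H2",
  "InChI=1S/C6H12N2O2/c1-5(9)7-3-4-8-6(2)10/h3-4H2,1-2H3,(H,7,9)(H,8,10)",
  "InChI=1S/C9H11NO/c1-8(11)10(2)9-6-4-3-5-7-9/h3-7H,1-2H3"
 ],
 "rule_counts": {
  "amide@1": 8,
  "buchwald@1": 4,
  "suzuki@1": 1,
  "amide@2": 13,
  "buchwald@2": 7
 },
 "elimination_keep": 5,
 "elimination_trace": [
  [
   "boronic_phenyl",
   0.1111111111111111,
   12,
   35.5
  ],
  [
   "amine_benzyl",
   0.42857142857142855,
   9,
   28.5
  ],
  [
   "arx_bromobenzene",
   0.375,
   6,
   20.5
  ]
 ],
 "retained": [
  "acid_acetic",
  "acid_benzoic",
  "amine_aniline",
  "amine_ethylenediamine",
  "amine_methyl"
 ]
}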