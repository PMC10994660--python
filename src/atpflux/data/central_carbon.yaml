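# Central-carbon metabolism network for hematopoietic stem cell flux analysis.
#
# Glycolysis, oxidative + non-oxidative pentose phosphate pathway, TCA cycle
# with pyruvate carboxylase anaplerosis, lactate dehydrogenase and lactate
# efflux, a nucleotide-synthesis (R5P) drain, an alpha-ketoglutarate
# biosynthetic drain, and a fatty-acid-derived acetyl-CoA supply.  Several
# steps are lumped into single reactions where the intermediate pools carry
# no extra labeling information: GAPDH+PGK (GAPDH), PGM+enolase (PGM_ENO),
# G6PD+6PGD oxidative branch (G6PD), aconitase+IDH (IDH).
#
# Atom maps use the conventional carbon transitions of the EMU literature:
# one lowercase letter per carbon, substrate letters mapped bijectively onto
# product letters.  Succinate and fumarate are rotationally symmetric; they
# are listed under `symmetric` and producers are scrambled 50/50.
name: central_carbon
metabolites:
  G6P: 6
  F6P: 6
  FBP: 6
  DHAP: 3
  GAP: 3
  PG3: 3
  PEP: 3
  PYR: 3
  LAC: 3
  ACCOA: 2
  OAA: 4
  CIT: 6
  AKG: 5
  SUC: 4
  FUM: 4
  MAL: 4
  RU5P: 5
  R5P: 5
  X5P: 5
  S7P: 7
  E4P: 4
  CO2: 1
externals:
  GLC: 6
  FA: 2
symmetric: [SUC, FUM]
substrate_labeling:
  GLC:
    - {pattern: "111111", fraction: 1.0}
  FA:
    - {pattern: "00", fraction: 1.0}
reactions:
  - {name: HK,      equation: "GLC/abcdef -> G6P/abcdef"}
  - {name: PGI,     equation: "G6P/abcdef -> F6P/abcdef", reversible: true}
  - {name: PFK,     equation: "F6P/abcdef -> FBP/abcdef"}
  - {name: ALD,     equation: "FBP/abcdef -> DHAP/cba + GAP/def", reversible: true}
  - {name: TPI,     equation: "DHAP/abc -> GAP/cba", reversible: true}
  - {name: GAPDH,   equation: "GAP/abc -> PG3/abc", reversible: true}
  - {name: PGM_ENO, equation: "PG3/abc -> PEP/abc", reversible: true}
  - {name: PK,      equation: "PEP/abc -> PYR/abc"}
  - {name: LDH,     equation: "PYR/abc -> LAC/abc", reversible: true}
  - {name: LAC_out, equation: "LAC/abc ->"}
  - {name: G6PD,    equation: "G6P/abcdef -> RU5P/bcdef + CO2/a"}
  - {name: RPI,     equation: "RU5P/abcde -> R5P/abcde", reversible: true}
  - {name: RPE,     equation: "RU5P/abcde -> X5P/abcde", reversible: true}
  - {name: TKT1,    equation: "X5P/abcde + R5P/fghij -> S7P/abfghij + GAP/cde", reversible: true}
  - {name: TAL,     equation: "S7P/abcdefg + GAP/hij -> E4P/defg + F6P/abchij", reversible: true}
  - {name: TKT2,    equation: "X5P/abcde + E4P/fghi -> F6P/abfghi + GAP/cde", reversible: true}
  - {name: R5P_out, equation: "R5P/abcde ->"}
  - {name: PDH,     equation: "PYR/abc -> ACCOA/bc + CO2/a"}
  - {name: PC,      equation: "PYR/abc + CO2/d -> OAA/abcd"}
  - {name: FAO,     equation: "FA/ab -> ACCOA/ab"}
  - {name: CS,      equation: "OAA/abcd + ACCOA/ef -> CIT/abcdef"}
  - {name: IDH,     equation: "CIT/abcdef -> AKG/bcdef + CO2/a"}
  - {name: AKGDH,   equation: "AKG/abcde -> SUC/bcde + CO2/a"}
  - {name: SDH,     equation: "SUC/abcd -> FUM/abcd", reversible: true}
  - {name: FUMASE,  equation: "FUM/abcd -> MAL/abcd", reversible: true}
  - {name: MDH,     equation: "MAL/abcd -> OAA/abcd", reversible: true}
  - {name: AKG_out, equation: "AKG/abcde ->"}
  - {name: CO2_out, equation: "CO2/a ->"}
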