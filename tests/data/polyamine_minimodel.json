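{
 "id": "polyamine_minimodel",
 "metabolites": [
  {
   "id": "met_L",
   "name": "L-methionine",
   "compartment": "c"
  },
  {
   "id": "arg_L",
   "name": "L-arginine",
   "compartment": "c"
  },
  {
   "id": "glu5sa",
   "name": "L-glutamate 5-semialdehyde",
   "compartment": "c"
  },
  {
   "id": "pi",
   "name": "phosphate",
   "compartment": "c"
  },
  {
   "id": "prpp",
   "name": "5-phospho-alpha-D-ribose 1-diphosphate",
   "compartment": "c"
  },
  {
   "id": "atp",
   "name": "ATP",
   "compartment": "c"
  },
  {
   "id": "precursor",
   "name": "generic biomass precursor",
   "compartment": "c"
  },
  {
   "id": "sam",
   "name": "S-adenosyl-L-methionine",
   "compartment": "c"
  },
  {
   "id": "dcsam",
   "name": "decarboxylated SAM",
   "compartment": "c"
  },
  {
   "id": "orn",
   "name": "ornithine",
   "compartment": "c"
  },
  {
   "id": "ptrc",
   "name": "putrescine",
   "compartment": "c"
  },
  {
   "id": "spmd",
   "name": "spermidine",
   "compartment": "c"
  },
  {
   "id": "sprm",
   "name": "spermine",
   "compartment": "c"
  },
  {
   "id": "mta",
   "name": "5'-methylthioadenosine",
   "compartment": "c"
  },
  {
   "id": "ade",
   "name": "adenine",
   "compartment": "c"
  },
  {
   "id": "mtr1p",
   "name": "5-methylthio-D-ribose 1-phosphate",
   "compartment": "c"
  },
  {
   "id": "adn",
   "name": "adenosine",
   "compartment": "c"
  },
  {
   "id": "amp",
   "name": "AMP",
   "compartment": "c"
  },
  {
   "id": "co2",
   "name": "CO2",
   "compartment": "c"
  },
  {
   "id": "ppi",
   "name": "diphosphate",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_met_L",
   "name": "met_L exchange",
   "stoichiometry": {
    "met_L": -1
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "EX_arg_L",
   "name": "arg_L exchange",
   "stoichiometry": {
    "arg_L": -1
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "EX_glu5sa",
   "name": "glu5sa exchange",
   "stoichiometry": {
    "glu5sa": -1
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "EX_pi",
   "name": "pi exchange",
   "stoichiometry": {
    "pi": -1
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "EX_prpp",
   "name": "prpp exchange",
   "stoichiometry": {
    "prpp": -1
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "EX_atp",
   "name": "atp exchange",
   "stoichiometry": {
    "atp": -1
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "EX_precursor",
   "name": "precursor exchange",
   "stoichiometry": {
    "precursor": -1
   },
   "lower_bound": -10.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "SK_mtr1p",
   "name": "mtr1p sink",
   "stoichiometry": {
    "mtr1p": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "SK_adn",
   "name": "adn sink",
   "stoichiometry": {
    "adn": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "SK_amp",
   "name": "amp sink",
   "stoichiometry": {
    "amp": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "SK_co2",
   "name": "co2 sink",
   "stoichiometry": {
    "co2": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "SK_ppi",
   "name": "ppi sink",
   "stoichiometry": {
    "ppi": -1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "",
   "is_exchange": true
  },
  {
   "id": "R_MAT",
   "name": "methionine adenosyltransferase",
   "stoichiometry": {
    "met_L": -1,
    "atp": -1,
    "sam": 1,
    "pi": 1,
    "ppi": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "MAT1A or (MAT2A and MAT2B)",
   "is_exchange": false
  },
  {
   "id": "R_AMD1",
   "name": "adenosylmethionine decarboxylase",
   "stoichiometry": {
    "sam": -1,
    "dcsam": 1,
    "co2": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "AMD1",
   "is_exchange": false
  },
  {
   "id": "R_ARG1",
   "name": "arginase",
   "stoichiometry": {
    "arg_L": -1,
    "orn": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "ARG1",
   "is_exchange": false
  },
  {
   "id": "R_OAT",
   "name": "ornithine transaminase (reversible)",
   "stoichiometry": {
    "glu5sa": -1,
    "orn": 1
   },
   "lower_bound": -1000.0,
   "upper_bound": 1000.0,
   "reversible": true,
   "gpr": "OAT",
   "is_exchange": false
  },
  {
   "id": "R_ODC1",
   "name": "ornithine decarboxylase",
   "stoichiometry": {
    "orn": -1,
    "ptrc": 1,
    "co2": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "ODC1",
   "is_exchange": false
  },
  {
   "id": "R_SRM",
   "name": "spermidine synthase",
   "stoichiometry": {
    "ptrc": -1,
    "dcsam": -1,
    "spmd": 1,
    "mta": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "SRM",
   "is_exchange": false
  },
  {
   "id": "R_SMS",
   "name": "spermine synthase",
   "stoichiometry": {
    "spmd": -1,
    "dcsam": -1,
    "sprm": 1,
    "mta": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "SMS",
   "is_exchange": false
  },
  {
   "id": "R_MTAP",
   "name": "5'-methylthioadenosine phosphorylase",
   "stoichiometry": {
    "mta": -1,
    "pi": -1,
    "ade": 1,
    "mtr1p": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "MTAP",
   "is_exchange": false
  },
  {
   "id": "R_APRT",
   "name": "adenine phosphoribosyltransferase",
   "stoichiometry": {
    "ade": -1,
    "prpp": -1,
    "amp": 1,
    "ppi": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "APRT",
   "is_exchange": false
  },
  {
   "id": "R_PNP_ade",
   "name": "purine-nucleoside phosphorylase on adenine (mis-annotation)",
   "stoichiometry": {
    "ade": -1,
    "adn": 1
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "PNP",
   "is_exchange": false
  },
  {
   "id": "R_BIOMASS",
   "name": "biomass equation",
   "stoichiometry": {
    "precursor": -1,
    "ptrc": "-1/100",
    "spmd": "-1/100",
    "sprm": "-1/100"
   },
   "lower_bound": 0.0,
   "upper_bound": 1000.0,
   "reversible": false,
   "gpr": "",
   "is_exchange": false
  }
 ],
 "genes": [
  "AMD1",
  "APRT",
  "ARG1",
  "MAT1A",
  "MAT2A",
  "MAT2B",
  "MTAP",
  "OAT",
  "ODC1",
  "PNP",
  "SMS",
  "SRM"
 ],
 "biomass_reaction_id": "R_BIOMASS",
 "medium": {
  "EX_arg_L": 10.0,
  "EX_atp": 10.0,
  "EX_glu5sa": 10.0,
  "EX_met_L": 10.0,
  "EX_pi": 10.0,
  "EX_precursor": 10.0,
  "EX_prpp": 10.0
 }
}
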