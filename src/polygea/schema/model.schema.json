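{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "polygea metabolic model JSON dialect",
 "description": "A documented subset of the community COBRA-JSON schema. Stoichiometric coefficients may be integers, decimal numbers, or exact-fraction strings like '1/3'. Exchange/sink reactions touch exactly one metabolite; with the 'met -> boundary' convention, negative flux is uptake and the medium map sets maximal intake (lower bound = -intake).",
 "type": "object",
 "required": ["metabolites", "reactions", "genes", "biomass_reaction_id"],
 "properties": {
  "id": {"type": "string"},
  "metabolites": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id"],
    "properties": {
     "id": {"type": "string", "minLength": 1},
     "name": {"type": "string"},
     "compartment": {"type": "string"}
    }
   }
  },
  "reactions": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "stoichiometry"],
    "properties": {
     "id": {"type": "string", "minLength": 1},
     "name": {"type": "string"},
     "stoichiometry": {
      "type": "object",
      "additionalProperties": {
       "oneOf": [
        {"type": "number"},
        {"type": "string", "pattern": "^-?[0-9]+(/[0-9]+)?$"}
       ]
      }
     },
     "lower_bound": {"type": "number"},
     "upper_bound": {"type": "number"},
     "reversible": {"type": "boolean"},
     "gpr": {
      "type": "string",
      "description": "Boolean gene rule: identifiers, parentheses, and/or (case-insensitive); empty string = no gene association. 'not' is rejected."
     },
     "is_exchange": {"type": "boolean"}
    }
   }
  },
  "genes": {"type": "array", "items": {"type": "string"}},
  "biomass_reaction_id": {"type": "string", "minLength": 1},
  "medium": {
   "type": "object",
   "additionalProperties": {"type": "number", "minimum": 0},
   "description": "exchange reaction id -> maximal intake flux (mmol/gDW/h)"
  }
 }
}
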