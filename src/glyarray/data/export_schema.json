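{
 "$id": "glyarray-dataset/1",
 "description": "Processed glycan-array dataset export",
 "type": "object",
 "required": ["schema", "analyte_ref", "options", "provenance", "intensities"],
 "properties": {
  "schema": {"type": "string", "const": "glyarray-dataset/1"},
  "analyte_ref": {"type": "string"},
  "options": {"type": "object"},
  "provenance": {"type": "object"},
  "rejects": {"type": "array"},
  "intensities": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["probe_key", "n_spots", "n_used", "value", "sd", "percent_cv"],
    "properties": {
     "probe_key": {"type": "string"},
     "concentration": {"type": ["string", "null"]},
     "dose": {"type": ["string", "null"]},
     "block": {"type": ["integer", "null"]},
     "n_spots": {"type": "integer"},
     "n_used": {"type": "integer"},
     "value": {"type": "number"},
     "sd": {"type": "number"},
     "percent_cv": {"type": ["number", "string"]},
     "excluded": {"type": "array"},
     "notes": {"type": "array"}
    }
   }
  }
 }
}
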