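{
 "version": "1.0",
 "guideline": "MIRAGE glycan microarray reporting guidelines (checklist categories paraphrased from the published glycan-array guideline headings)",
 "categories": [
  {"category": "sample description", "record": "analyte", "fields": ["name"]},
  {"category": "sample origin", "record": "analyte", "fields": ["origin"]},
  {"category": "database identifiers", "record": "analyte", "fields": ["database_ids"]},
  {"category": "sample purity and quality control", "record": "analyte", "fields": ["purity", "qc_info"]},
  {"category": "analyte concentration", "record": "analyte", "fields": ["concentration_used"]},
  {"category": "detection system", "record": "analyte", "fields": ["detection_system"]},
  {"category": "assay protocol", "record": "experiment", "fields": ["protocol_steps"]},
  {"category": "scanner settings", "record": "experiment", "fields": ["scanner_settings"]},
  {"category": "array batch", "record": "experiment", "fields": ["array_batch"]},
  {"category": "assay date", "record": "experiment", "fields": ["assay_date"]},
  {"category": "glycan probe list", "record": "array", "fields": ["probes"]},
  {"category": "array layout", "record": "array", "fields": ["geometry"]}
 ]
}
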