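probe_key,name,sequence_cfg_iupac,sequence_2d_text,sequence_gws,sequence_wurcs,sequence_glycoct,glytoucan_id,tag_name,tag_description,probe_class
PROBE-001,3'-sialyllactose NGL,NeuAca-3Galb-4Glcb,,,,,,DH,"reductive-amination lipid tag",defined-glycan
PROBE-002,Glycoprotein fraction,,,,,,,,,undefined-or-fraction
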