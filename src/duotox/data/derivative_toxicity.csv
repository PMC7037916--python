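compound_id,ec50,loec
CIP,2793.44,1.40e-8
3-CH2-C3H5-CIP,1331.09,9.66e-9
3-CH2-C3H4Cl-CIP,1097.87,9.55e-9
3-CH2CH2CH3-CIP,2581.52,1.07e-8
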