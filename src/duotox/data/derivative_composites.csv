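compound_id,composite
CIP,-0.604
3-CH2-C3H5-CIP,-0.489
3-CH2-C3H4Cl-CIP,-0.529
3-CH2CH2CH3-CIP,-0.530
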