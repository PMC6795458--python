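code,requires_antibiotics
J00,false
J01,false
J02,false
J03,false
J04,false
J05,false
J06,false
J09,false
J10,false
J11,false
J12,false
J13,true
J14,true
J15,true
J16,true
J17,true
J18,true
J20,false
J21,false
J22,false
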