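subject_id,pss
S01,11
S02,25
S03,16
S04,9
S05,10
S06,22
S07,18
S08,7
S09,21
S10,9
S11,12
S12,17
S13,8
S14,13
S15,17
S16,23
S17,12
S18,6
S19,18
S20,12
S21,12
S22,13
S23,26
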