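# synthetic placeholder gene list for the CIN70 proliferation signature
CIN70_S01
CIN70_S02
CIN70_S03
CIN70_S04
CIN70_S05
CIN70_S06
CIN70_S07
CIN70_S08
CIN70_S09
CIN70_S10
CIN70_S11
CIN70_S12
CIN70_S13
CIN70_S14
CIN70_S15
CIN70_S16
CIN70_S17
CIN70_S18
CIN70_S19
CIN70_S20
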