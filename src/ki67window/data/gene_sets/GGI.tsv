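# synthetic placeholder gene list for the GGI proliferation signature
GGI_S01
GGI_S02
GGI_S03
GGI_S04
GGI_S05
GGI_S06
GGI_S07
GGI_S08
GGI_S09
GGI_S10
GGI_S11
GGI_S12
GGI_S13
GGI_S14
GGI_S15
GGI_S16
GGI_S17
GGI_S18
GGI_S19
GGI_S20
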