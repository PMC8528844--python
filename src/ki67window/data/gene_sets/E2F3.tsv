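# synthetic placeholder gene list for the E2F3 proliferation signature
E2F3_S01
E2F3_S02
E2F3_S03
E2F3_S04
E2F3_S05
E2F3_S06
E2F3_S07
E2F3_S08
E2F3_S09
E2F3_S10
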