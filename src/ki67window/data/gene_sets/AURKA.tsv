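# synthetic placeholder gene list for the AURKA proliferation signature
MKI67
AURKA_S01
AURKA_S02
AURKA_S03
AURKA_S04
AURKA_S05
AURKA_S06
AURKA_S07
AURKA_S08
AURKA_S09
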