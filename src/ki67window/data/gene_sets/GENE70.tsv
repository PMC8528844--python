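# synthetic placeholder gene list for the GENE70 proliferation signature
GENE70_S01	1
GENE70_S02	1
GENE70_S03	1
GENE70_S04	1
GENE70_S05	1
GENE70_S06	1
GENE70_S07	1
GENE70_S08	1
GENE70_S09	1
GENE70_S10	1
GENE70_S11	-1
GENE70_S12	-1
GENE70_S13	-1
GENE70_S14	-1
GENE70_S15	-1
GENE70_S16	-1
GENE70_S17	-1
GENE70_S18	-1
GENE70_S19	-1
GENE70_S20	-1
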