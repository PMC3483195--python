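(Sce:1.0,(Mbr:1.0,((Tsp:0.62,(Cbr:0.09,Cel:0.09):0.55):0.13,((Bmo:0.38,(Aae:0.28,Dme:0.33):0.14):0.18,(Gga:0.12,(Hsa:0.05,Mmu:0.06):0.09):0.33):0.09):0.16):1.0);
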