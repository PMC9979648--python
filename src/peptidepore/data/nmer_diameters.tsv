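# Modeled pore diameters of n-mer beta-barrel assemblies (HOLE-style lookup).
n	diameter_nm
5	1.1
6	1.5
7	1.7
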