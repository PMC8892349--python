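program,component,kg_per_mmbtu,g_per_mj
this_study,domestic_luc,40.9,38.7
ria,domestic_luc,-4.0,-3.8
ria,international_luc,31.8,30.1
lcfs,combined_luc,20.9,19.8
greet,domestic_luc,2.1,2.0
greet,international_luc,5.7,5.4
ria,total,77.2,73.2
lcfs,total,74.9,71.0
greet,total,56.6,53.6
ria,gasoline,98.2,93.1
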