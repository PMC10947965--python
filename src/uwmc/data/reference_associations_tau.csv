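region_a,region_b,beta_full,p_full,beta_ba,p_ba,beta_nhw,p_nhw,interaction_p
L inferior temporal gyrus,R parahippocampal gyrus,-2.26,0.0008,-2.40,0.001,-1.98,0.01,
L fusiform gyrus,R entorhinal cortex,-1.89,0.0003,-1.85,0.007,-2.22,0.01,
L amygdala,L fusiform gyrus,-0.97,0.008,-0.98,0.06,-1.43,0.01,0.94
L amygdala,L inferior temporal gyrus,-0.95,0.006,-0.76,0.12,-1.39,0.01,0.38
L inferior temporal gyrus,L parahippocampal gyrus,-0.66,0.06,-0.30,0.54,-0.91,0.08,
L fusiform gyrus,L middle temporal gyrus,-0.64,0.03,-0.14,0.73,-1.37,0.003,0.15
L fusiform gyrus,L parahippocampal gyrus,-0.46,0.13,0.39,0.39,-1.14,0.009,0.06
L amygdala,R fusiform gyrus,0.23,0.09,0.33,0.06,0.14,0.52,
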