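region_a,region_b,beta_full,p_full,beta_ba,p_ba,beta_nhw,p_nhw,interaction_p
L caudal anterior cingulate cortex,L caudal middle frontal gyrus,-1.08,0.006,-1.39,0.01,-0.92,0.14,0.29
L superior frontal gyrus,R rostral middle frontal gyrus,-1.19,0.0004,-1.20,0.03,-1.25,0.009,
L rostral middle frontal gyrus,R caudal anterior cingulate cortex,-1.09,0.002,-0.96,0.06,-1.31,0.01,0.75
L lateral orbitofrontal gyrus,L rostral anterior cingulate cortex,-1.08,0.0009,-1.36,0.004,-1.04,0.04,0.80
L pars orbitalis,R caudal anterior cingulate cortex,-1.01,0.008,-0.89,0.09,-1.37,0.03,0.74
L frontal pole,R supramarginal gyrus,-2.44,0.02,-2.55,0.01,,,
R superior frontal gyrus,R inferior parietal gyrus,-1.52,0.0001,-1.69,0.0002,-1.41,0.005,
L caudal middle frontal gyrus,R precuneus,-1.36,0.0003,-0.73,0.16,-2.42,0.0001,0.12
R pars orbitalis,R precuneus,-1.34,0.0007,-1.04,0.06,-1.97,0.002,0.25
L rostral middle frontal gyrus,R anterior ventral striatum,-1.24,0.005,-1.01,0.11,-1.58,0.02,0.44
L pars triangularis,R anterior ventral striatum,-0.55,0.32,0.53,0.57,-1.33,0.07,
L rostral anterior cingulate cortex,R banks of superior temporal sulcus,-2.03,0.02,-1.09,0.35,-2.60,0.05,
R superior frontal gyrus,R superior temporal gyrus,-1.55,0.0001,-1.84,0.0001,-1.47,0.0004,
R caudal middle frontal gyrus,R banks of superior temporal sulcus,-1.32,0.006,-1.15,0.09,-1.73,0.02,0.81
R caudal middle frontal gyrus,R superior temporal gyrus,-1.24,0.001,-1.24,0.03,-1.61,0.004,0.78
R isthmus cingulate cortex,L insula,-0.88,0.02,-0.68,0.18,-1.23,0.04,
L isthmus cingulate cortex,R anterior ventral striatum,-3.03,0.0001,-2.01,0.08,-3.57,0.0001,0.18
R banks of superior temporal sulcus,R insula,-1.24,0.0005,-1.04,0.04,-1.81,0.0007,0.55
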