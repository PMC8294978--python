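nv_id,patient,age,eye,n_initial_injections,posttreatment_week,last_week,change_structure_post,change_structure_last,change_angio_post,change_angio_last,fd_structure_baseline,fd_structure_post,fd_structure_last,fd_angio_baseline,fd_angio_post,fd_angio_last,structure_area_baseline_mm2,structure_area_post_mm2,structure_area_last_mm2,angio_area_baseline_mm2,angio_area_post_mm2,angio_area_last_mm2
NV1,A,59,right,4,17,46,-51,-53,-76,-83,64,38,28,81,69,59,1.0,0.49,0.47,1.0,0.24,0.17
NV2,A,59,left,4,17,45,-8,-3,-78,-85,62,25,16,62,66,75,1.0,0.92,0.97,1.0,0.22,0.15
NV3,B,30,right,3,13,50,-100,-100,-100,-100,61,0,0,62,0,0,1.0,0.0,0.0,1.0,0.0,0.0
NV4,B,30,left,3,13,51,12,-27,-11,13,81,42,40,89,51,53,1.0,1.12,0.73,1.0,0.89,1.13
NV5,C,48,right,3,13,19,28,196,-65,-20,82,52,49,71,58,54,1.0,1.28,2.96,1.0,0.35,0.8
NV6,C,48,left,3,13,23,-15,-17,-24,-38,79,26,41,82,36,57,1.0,0.85,0.83,1.0,0.76,0.62
NV7,D,49,left,3,13,44,16,-6,-32,-34,44,30,41,48,38,45,1.0,1.16,0.94,1.0,0.68,0.66
NV8,E,51,right,3,13,48,-23,52,-33,-30,76,73,27,79,84,54,1.0,0.77,1.52,1.0,0.67,0.7
NV9,E,51,right,3,13,29,-27,3,-48,-2,72,65,70,72,83,73,1.0,0.73,1.03,1.0,0.52,0.98
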