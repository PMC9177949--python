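roi_label,x,y,z
Precentral_L,0.0,0.0,0.0
Precentral_R,41.37,-8.21,52.09
Frontal_Sup_L,0.0,0.0,0.0
Frontal_Sup_R,21.9,31.12,43.82
Frontal_Sup_Orb_L,0.0,0.0,0.0
Frontal_Sup_Orb_R,0.0,0.0,0.0
Frontal_Mid_L,0.0,0.0,0.0
Frontal_Mid_R,0.0,0.0,0.0
Frontal_Mid_Orb_L,0.0,0.0,0.0
Frontal_Mid_Orb_R,0.0,0.0,0.0
Frontal_Inf_Oper_L,0.0,0.0,0.0
Frontal_Inf_Oper_R,50.2,14.98,21.41
Frontal_Inf_Tri_L,0.0,0.0,0.0
Frontal_Inf_Tri_R,50.33,30.16,14.17
Frontal_Inf_Orb_L,0.0,0.0,0.0
Frontal_Inf_Orb_R,0.0,0.0,0.0
Rolandic_Oper_L,0.0,0.0,0.0
Rolandic_Oper_R,52.65,-6.25,14.63
Supp_Motor_Area_L,-5.32,4.85,61.38
Supp_Motor_Area_R,8.62,0.17,61.85
Olfactory_L,0.0,0.0,0.0
Olfactory_R,0.0,0.0,0.0
Frontal_Sup_Medial_L,-4.8,49.17,30.89
Frontal_Sup_Medial_R,9.1,50.84,30.22
Frontal_Med_Orb_L,0.0,0.0,0.0
Frontal_Med_Orb_R,0.0,0.0,0.0
Rectus_L,0.0,0.0,0.0
Rectus_R,0.0,0.0,0.0
Insula_L,0.0,0.0,0.0
Insula_R,39.02,6.25,2.08
Cingulum_Ant_L,0.0,0.0,0.0
Cingulum_Ant_R,0.0,0.0,0.0
Cingulum_Mid_L,0.0,0.0,0.0
Cingulum_Mid_R,0.0,0.0,0.0
Cingulum_Post_L,0.0,0.0,0.0
Cingulum_Post_R,0.0,0.0,0.0
Hippocampus_L,0.0,0.0,0.0
Hippocampus_R,0.0,0.0,0.0
ParaHippocampal_L,0.0,0.0,0.0
ParaHippocampal_R,0.0,0.0,0.0
Amygdala_L,0.0,0.0,0.0
Amygdala_R,0.0,0.0,0.0
Calcarine_L,0.0,0.0,0.0
Calcarine_R,0.0,0.0,0.0
Cuneus_L,-5.93,-80.13,27.22
Cuneus_R,0.0,0.0,0.0
Lingual_L,0.0,0.0,0.0
Lingual_R,0.0,0.0,0.0
Occipital_Sup_L,-16.54,-84.26,28.17
Occipital_Sup_R,0.0,0.0,0.0
Occipital_Mid_L,-32.39,-80.73,16.11
Occipital_Mid_R,0.0,0.0,0.0
Occipital_Inf_L,-36.36,-78.29,-7.84
Occipital_Inf_R,0.0,0.0,0.0
Fusiform_L,-31.16,-40.3,-20.23
Fusiform_R,0.0,0.0,0.0
Postcentral_L,0.0,0.0,0.0
Postcentral_R,41.43,-25.49,52.55
Parietal_Sup_L,0.0,0.0,0.0
Parietal_Sup_R,0.0,0.0,0.0
Parietal_Inf_L,0.0,0.0,0.0
Parietal_Inf_R,46.46,-46.29,49.54
SupraMarginal_L,-55.79,-33.64,30.45
SupraMarginal_R,0.0,0.0,0.0
Angular_L,0.0,0.0,0.0
Angular_R,0.0,0.0,0.0
Precuneus_L,-7.24,-56.07,48.01
Precuneus_R,9.98,-56.05,43.77
Paracentral_Lobule_L,-7.63,-25.36,70.07
Paracentral_Lobule_R,7.48,-31.59,68.09
Caudate_L,0.0,0.0,0.0
Caudate_R,0.0,0.0,0.0
Putamen_L,0.0,0.0,0.0
Putamen_R,0.0,0.0,0.0
Pallidum_L,0.0,0.0,0.0
Pallidum_R,0.0,0.0,0.0
Thalamus_L,0.0,0.0,0.0
Thalamus_R,0.0,0.0,0.0
Heschl_L,0.0,0.0,0.0
Heschl_R,0.0,0.0,0.0
Temporal_Sup_L,-53.16,-20.68,7.13
Temporal_Sup_R,58.15,-21.78,6.8
Temporal_Pole_Sup_L,-39.88,15.14,-20.18
Temporal_Pole_Sup_R,0.0,0.0,0.0
Temporal_Mid_L,-55.52,-33.8,-2.2
Temporal_Mid_R,57.47,-37.23,-1.47
Temporal_Pole_Mid_L,-36.32,14.59,-34.08
Temporal_Pole_Mid_R,0.0,0.0,0.0
Temporal_Inf_L,0.0,0.0,0.0
Temporal_Inf_R,0.0,0.0,0.0
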