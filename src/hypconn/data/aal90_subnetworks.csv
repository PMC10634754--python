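roi_name,hemisphere,subnetwork
Precentral_L,L,SMN
Precentral_R,R,SMN
Frontal_Sup_L,L,FPN
Frontal_Sup_R,R,FPN
Frontal_Sup_Orb_L,L,aDMN
Frontal_Sup_Orb_R,R,aDMN
Frontal_Mid_L,L,FPN
Frontal_Mid_R,R,FPN
Frontal_Mid_Orb_L,L,aDMN
Frontal_Mid_Orb_R,R,aDMN
Frontal_Inf_Oper_L,L,VAN
Frontal_Inf_Oper_R,R,VAN
Frontal_Inf_Tri_L,L,FPN
Frontal_Inf_Tri_R,R,FPN
Frontal_Inf_Orb_L,L,FPN
Frontal_Inf_Orb_R,R,FPN
Rolandic_Oper_L,L,SMN
Rolandic_Oper_R,R,SMN
Supp_Motor_Area_L,L,SMN
Supp_Motor_Area_R,R,SMN
Olfactory_L,L,SN
Olfactory_R,R,SN
Frontal_Sup_Medial_L,L,aDMN
Frontal_Sup_Medial_R,R,aDMN
Frontal_Med_Orb_L,L,aDMN
Frontal_Med_Orb_R,R,aDMN
Rectus_L,L,aDMN
Rectus_R,R,aDMN
Insula_L,L,SN
Insula_R,R,SN
Cingulum_Ant_L,L,aDMN
Cingulum_Ant_R,R,aDMN
Cingulum_Mid_L,L,SN
Cingulum_Mid_R,R,SN
Cingulum_Post_L,L,pDMN
Cingulum_Post_R,R,pDMN
Hippocampus_L,L,pDMN
Hippocampus_R,R,pDMN
ParaHippocampal_L,L,pDMN
ParaHippocampal_R,R,pDMN
Amygdala_L,L,SN
Amygdala_R,R,SN
Calcarine_L,L,VN
Calcarine_R,R,VN
Cuneus_L,L,VN
Cuneus_R,R,VN
Lingual_L,L,VN
Lingual_R,R,VN
Occipital_Sup_L,L,VN
Occipital_Sup_R,R,VN
Occipital_Mid_L,L,VN
Occipital_Mid_R,R,VN
Occipital_Inf_L,L,VN
Occipital_Inf_R,R,VN
Fusiform_L,L,VN
Fusiform_R,R,VN
Postcentral_L,L,SMN
Postcentral_R,R,SMN
Parietal_Sup_L,L,DAN
Parietal_Sup_R,R,DAN
Parietal_Inf_L,L,DAN
Parietal_Inf_R,R,DAN
SupraMarginal_L,L,VAN
SupraMarginal_R,R,VAN
Angular_L,L,pDMN
Angular_R,R,pDMN
Precuneus_L,L,pDMN
Precuneus_R,R,pDMN
Paracentral_Lobule_L,L,SMN
Paracentral_Lobule_R,R,SMN
Caudate_L,L,FPN
Caudate_R,R,FPN
Putamen_L,L,SMN
Putamen_R,R,SMN
Pallidum_L,L,SMN
Pallidum_R,R,SMN
Thalamus_L,L,SMN
Thalamus_R,R,SMN
Heschl_L,L,SMN
Heschl_R,R,SMN
Temporal_Sup_L,L,VAN
Temporal_Sup_R,R,VAN
Temporal_Pole_Sup_L,L,VAN
Temporal_Pole_Sup_R,R,VAN
Temporal_Mid_L,L,pDMN
Temporal_Mid_R,R,pDMN
Temporal_Pole_Mid_L,L,aDMN
Temporal_Pole_Mid_R,R,aDMN
Temporal_Inf_L,L,DAN
Temporal_Inf_R,R,DAN
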