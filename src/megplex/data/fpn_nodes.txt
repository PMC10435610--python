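# Frontoparietal node set — STAND-IN default, edit to match your parcellation.
# A plausible bilateral frontoparietal selection from the default 78-region
# label list; replace with your own membership file via --subnet.
Frontal_Sup_L
Frontal_Sup_R
Frontal_Mid_L
Frontal_Mid_R
Frontal_Inf_Tri_L
Frontal_Inf_Tri_R
Parietal_Sup_L
Parietal_Sup_R
Parietal_Inf_L
Parietal_Inf_R
SupraMarginal_L
SupraMarginal_R
Angular_L
Angular_R
Precuneus_L
Precuneus_R
Cingulum_Mid_L
Cingulum_Mid_R
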