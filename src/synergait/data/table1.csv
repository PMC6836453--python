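group,subject,prosthetic_knee,age_y,height_cm,weight_kg,speed_m_s
TF,1,C-Leg,56,175,72,0.93
TF,2,C-Leg,74,170,85,0.76
TF,3,C-Leg,72,163,87,0.80
TF,4,C-Leg,52,178,115,0.79
TF,5,C-Leg,53,183,67,0.82
TF,6,C-Leg,39,175,95,0.75
TF,7,C-Leg,36,170,70,1.17
TF,8,Genium,49,178,100,0.82
TF,9,Genium,29,172,65,1.12
TF,10,Genium,59,170,80,0.97
TF,11,Genium,44,192,103,1.16
TF,12,Genium,48,174,90,1.08
TF,13,Genium,69,175,76,0.45
TF,14,Genium,30,178,95,0.98
C_SS,1,,44,170,72,1.05
C_SS,2,,55,183,75,1.16
C_SS,3,,64,165,70,0.98
C_SS,4,,52,178,70,1.24
C_SS,5,,45,189,88,1.28
C_SS,6,,55,180,78,1.33
C_SS,7,,47,174,85,1.33
C_SS,8,,47,188,90,1.18
C_SS,9,,51,176,75,1.16
C_SS,10,,52,168,80,1.44
C_SS,11,,71,174,79,1.41
C_SS,12,,60,168,77,1.46
C_SL,1,,44,170,72,0.83
C_SL,2,,55,183,75,1.03
C_SL,3,,64,165,70,0.85
C_SL,4,,52,178,70,0.89
C_SL,5,,45,189,88,0.69
C_SL,6,,55,180,78,0.83
C_SL,7,,47,174,85,1.02
C_SL,8,,47,188,90,0.78
C_SL,9,,51,176,75,0.87
C_SL,10,,52,168,80,1.13
C_SL,11,,71,174,79,1.00
C_SL,12,,60,168,77,1.03
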