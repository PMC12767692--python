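rank,source_id,name,opposite_polarity,mean_causal_effect,evidence
1,1940,Upper lobe primary malignancy,true,-0.0129,Direct
2,1198,Lower lobe primary malignancy,true,-0.0071,Direct
3,886,Respiratory tract primary malignancy,true,-0.0061,Direct
4,1616,Unrecorded Race URI,false,-0.0047,Absent
5,227,Pregnancy Elevated Glucose Complications,true,-0.0040,Weak
6,1452,Bladder primary malignancy,true,-0.0033,Direct
7,1273,Congenital Anomalies,false,-0.0031,Direct/Weak
8,1158,Lovastatin,false,-0.0030,Strong
9,361,Treated Unstable Angina,false,-0.0028,Moderate
10,7,Postpartum Pregnancy No Complications,false,-0.0027,Absent
11,782,Croup vs. Infective Pneumonia,false,-0.0027,Weak
12,465,Adjustment Disorder with Anxiety,false,-0.0025,Weak
13,362,Bacteremia,false,-0.0024,Weak
14,343,COPD ICS LABA,false,-0.0023,Strong
15,638,"Respiratory malignancy, multiple locations",true,-0.0023,Direct
16,1962,ADHD Black Male,false,-0.0021,Moderate
17,1109,Infective Pneumonia,false,-0.0018,Moderate
18,864,COVID-19,true,-0.0018,Moderate
19,1936,COPD,true,-0.0018,Strong
20,1552,Elevated venous blood oxygen,false,-0.0017,Absent
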