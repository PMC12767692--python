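rank,source_id,name,opposite_polarity,mean_causal_effect,evidence
1,1936,COPD,false,0.0152,Strong
2,886,Respiratory tract primary malignancy,false,0.0136,Direct
3,1940,Upper lobe primary malignancy,false,0.0095,Direct
4,1198,Lower lobe primary malignancy,false,0.0067,Direct
5,1622,Indeterminate Pulmonary Nodule,false,0.0067,Absent
6,148,Hypertensive disorder,false,0.0044,Strong
7,1872,Nicotine dependence,false,0.0034,Strong
8,1452,Bladder primary malignancy,false,0.0034,Direct/Moderate
9,638,"Respiratory malignancy, multiple locations",false,0.0025,Direct
10,227,Pregnancy Elevated Glucose Complications,false,0.0022,Weak
11,343,COPD ICS LABA,true,0.0021,Strong
12,5,Tobacco dependence syndrome,false,0.0021,Strong
13,760,Histoplasmosis,true,0.0021,Direct
14,1066,Abnormal findings on lung imaging NOS,false,0.0020,Weak
15,1616,Unrecorded Race URI,true,0.0020,Absent
16,1158,Lovastatin,true,0.0020,Strong
17,979,Lung Disorder NOS,false,0.0019,Absent
18,1305,Age with elevated Hematocrit and other CV parameters,false,0.0018,Mixed
19,467,Post-inflammatory vs. idiopathic pulmonary fibrosis,false,0.0017,Strong
20,7,Postpartum Pregnancy No Complications,false,0.0017,Absent
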