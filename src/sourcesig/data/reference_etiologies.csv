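category,element,group_key,signature_ids
malignant,Adenocarcinoma,primary_lung_cancer,886;1198;1940
malignant,Squamous Cell Carcinoma,primary_lung_cancer,886;1198;1940
malignant,Large Cell Carcinoma,primary_lung_cancer,886;1198;1940
malignant,Small Cell Carcinoma,primary_lung_cancer,886;1198;1940
malignant,Metastatic Breast Cancer,metastatic_breast,203;236;403;546;566;654;880;919;971;982;1075;1076;1086;1110;1133;1180;1742;1762;1781
malignant,Metastatic Head and Neck Cancer,metastatic_head_neck,292;360;597;831;927;934;974;1607;1802;1938
malignant,Metastatic Melanoma,metastatic_melanoma,986;1120;1344;1470
malignant,Metastatic Colon Cancer,metastatic_colon,1341;1342;1945
malignant,Metastatic Kidney Cancer,metastatic_kidney,25;174;991;1349;1631;1722
malignant,Metastatic Sarcoma,metastatic_sarcoma,1457;1886;1953
malignant,Metastatic Germ Cell Tumor,metastatic_germ_cell,1132
malignant,Metastatic Others,metastatic_others,1452
malignant,Pulmonary Carcinoid Tumor,pulmonary_carcinoid,
benign,Histoplasmosis,histoplasmosis,760;995
benign,Coccidiomycosis,coccidiomycosis,
benign,Mycobacteria,mycobacteria,1096;1432
benign,Staph aureus Abscess,staph_abscess,
benign,Dirofilariasis,dirofilariasis,
benign,Pulmonary Hamartoma,hamartoma,
benign,Pulmonary Fibroma,fibroma,
benign,Pulmonary Leiomyoma,leiomyoma,
benign,Pulmonary Hemangioma,hemangioma,
benign,Amyloidoma,amyloidoma,
benign,Pneumocytoma,pneumocytoma,
benign,Pulmonary AVM,avm,
benign,Pulmonary Infarct,infarct,1568
benign,Pulmonary Hematoma,hematoma,
benign,Pulmonary Varix,varix,
benign,Granulomatosis with Polyangiitis,gpa,45
benign,Rheumatoid Arthritis,rheumatoid_arthritis,135;140;168;320;369;482;494;716;948;1049;1072;1296;1317;1357;1383;1581;1738;1845;1846;1866;1992
benign,Sarcoidosis,sarcoidosis,1961
benign,Rounded Atelectasis,rounded_atelectasis,
benign,Intrapulmonary Lymph Nodes,intrapulmonary_lymph_nodes,
benign,Developmental Lesions,developmental_lesions,1273
benign,Loculated Fluid,loculated_fluid,
benign,Mucoid Impaction,mucoid_impaction,
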