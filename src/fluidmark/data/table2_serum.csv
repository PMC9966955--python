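accession,uniprot,gene,name,ratio_BN,sig_BN,ratio_MN,sig_MN,ratio_MB,sig_MB,runs,peptides95,auc_pct
4502443,DYST,DST,Dystonin isoform 1e precursor,3.65,true,1.93,false,0.52,false,2,2,95.80
105990532,APOB,APOB,Apolipoprotein B-100 precursor,0.93,true,0.93,true,1.04,false,8,456,95.42
4504349,HBB,HBB,Hemoglobin subunit beta,0.78,false,1.97,true,2.04,true,6,5,93.73
4557871,TRFE,TF,Serotransferrin precursor,0.25,true,0.19,true,0.77,false,2,38,93.59
55743122,RET4,RBP4,Retinol-binding protein 4 precursor,1.40,false,1.48,true,1.03,false,8,54,93.48
936697130,PROS,PROS1,Vitamin K-dependent protein S isoform 1 precursor,0.78,true,1.04,false,1.28,false,8,20,93.48
578822814,A2MG,A2M,Alpha-2-macroglobulin isoform X1,0.96,true,0.94,true,0.97,false,8,684,92.39
767989245,CADH5,CDH5,Cadherin-5 isoform X1,1.50,true,1.18,false,0.80,false,8,5,91.60
89191868,VWF,VWF,Von Willebrand factor preproprotein,1.57,true,0.90,false,0.59,true,8,17,91.58
73858570,IC1,SERPING1,Plasma protease C1 inhibitor precursor,0.90,false,0.76,true,0.89,false,8,54,88.63
530366456,C4BPA,C4BPA,C4b-binding protein alpha chain isoform X1,0.66,true,0.87,false,1.29,false,8,16,86.41
7669550,VINC,VCL,Vinculin isoform meta-VCL,0.61,false,1.75,false,2.86,true,2,2,85.53
45580688,CO7,C7,Complement component C7 precursor,0.98,false,0.72,false,0.68,true,8,61,85.14
4503143,CATD,CTSD,Cathepsin D preproprotein,0.35,true,0.72,false,2.03,false,2,1,82.09
767934633,CO6,C6,Complement component C6 isoform X4,1.60,true,1.32,false,0.79,true,8,58,81.67
115298678,CO3,C3,Complement C3 preproprotein,0.97,false,0.95,true,0.96,false,8,809,80.78
32189392,PRDX2,PRDX2,Peroxiredoxin-2,1.89,true,2.16,true,1.11,false,6,9,80.24
530416417,APOC1,APOC1,Apolipoprotein C-I isoform a precursor,0.59,false,0.28,false,0.36,true,8,3,76.02
32130518,APOC2,APOC2,Apolipoprotein C-II precursor,0.69,false,0.69,true,1.06,false,8,23,75.30
15811782,GPKOW,GPKOW,G-patch domain and KOW motifs-containing protein,1.1,false,0.19,false,0.17,true,2,2,74.64
223671861,PROP,CFP,Properdin precursor,1.40,true,1.33,false,0.90,false,8,11,73.84
38016947,CO5,C5,Complement C5 isoform 1 preproprotein,0.68,true,0.75,false,1.08,false,6,73,72.95
40548420,COL11,COLEC11,Collectin-11 isoform b,0.31,true,0.55,false,1.73,false,2,2,72.86
73858566,HEP2,SERPIND1,Heparin cofactor 2 precursor,0.64,true,0.54,true,0.78,false,8,30,71.61
167857790,A1AG1,ORM1,Alpha-1-acid glycoprotein 1 precursor,2.39,false,3.47,true,1.31,false,8,88,69.22
21071030,A1BG,A1BG,Alpha-1B-glycoprotein precursor,1.66,true,1.54,true,0.93,false,8,183,67.10
514239916,CO8B,C8B,Complement component C8 beta chain isoform 1 preproprotein,0.58,false,0.54,true,1.00,false,6,26,66.92
4557321,APOA1,APOA1,Apolipoprotein A-I isoform 1 preproprotein,0.96,false,0.91,true,0.94,true,8,202,66.64
530375762,CPN2,CPN2,Carboxypeptidase N subunit 2 isoform X1,0.88,false,0.74,true,0.83,false,8,18,66.55
16418467,A2GL,LRG1,Leucine-rich alpha-2-glycoprotein precursor,1.26,false,1.49,true,1.17,false,8,26,66.10
4501987,AFAM,AFM,Afamin precursor,1.43,true,0.97,false,0.67,false,8,67,63.81
4502419,BLVRB,BLVRB,Flavin reductase (NADPH),0.94,false,3.13,true,3.31,false,2,1,62.79
11321561,HEMO,HPX,Hemopexin precursor,0.92,true,0.97,false,0.99,false,8,347,62.75
73858564,CBG,SERPINA6,Corticosteroid-binding globulin precursor,0.71,false,0.60,true,0.83,false,8,13,62.28
4505047,LUM,LUM,Lumican precursor,1.82,true,1.40,false,0.79,false,8,25,61.56
4503689,FIBA,FGA,Fibrinogen alpha chain isoform alpha-E preproprotein,1.37,true,2.03,true,1.34,false,8,23,61.18
4504893,KNG1,KNG1,Kininogen-1 isoform 2 precursor,1.21,false,0.83,false,0.7,true,8,102,59.04
8923909,ERBIN,ERBIN,Erbin isoform 2,2.26,false,0.78,false,0.34,true,2,1,58.76
33350932,DYHC1,DYNC1H1,Cytoplasmic dynein 1 heavy chain 1,0.22,true,0.37,false,1.64,false,2,2,57.99
573459745,KAIN,SERPINA4,Kallistatin isoform 2 precursor,0.67,true,0.64,true,0.91,false,8,20,57.95
530365618,CD5L,CD5L,CD5 antigen-like isoform X1,1.32,false,1.65,false,1.73,true,6,4,56.55
60499001,SOX,PIPOX,Peroxisomal sarcosine oxidase,0.35,false,0.23,true,0.66,false,2,1,55.97
767975372,CE290,CEP290,Centrosomal protein of 290 kDa isoform X6,2.83,true,2.81,false,0.98,false,2,3,55.70
40317626,TSP1,THBS1,Thrombospondin-1 precursor,0.56,true,0.76,false,1.30,false,6,30,55.48
767985152,TSP1,THBS1,Thrombospondin-1 isoform X2,0.55,true,0.30,true,0.58,true,2,29,55.48
767953771,MED30,MED30,Mediator of RNA polymerase II transcription subunit 30 isoform 3,0.52,false,0.28,true,0.82,false,6,4,54.62
4502337,ZA2G,AZGP1,Zinc-alpha-2-glycoprotein precursor,1.04,false,1.36,true,1.22,false,8,67,54.01
156523970,FETUA,AHSG,Alpha-2-HS-glycoprotein preproprotein,1.71,false,1.34,true,0.86,false,8,149,52.63
205277441,THBG,SERPINA7,Thyroxine-binding globulin precursor,0.66,true,0.60,true,0.80,false,8,20,52.62
189163530,A1AT,SERPINA1,Alpha-1-antitrypsin precursor,0.12,false,0.08,true,0.77,false,2,1,52.04
4502149,APOA2,APOA2,Apolipoprotein A-II preproprotein,0.90,false,0.50,true,0.50,true,8,119,51.83
190194360,PCD20,PCDH20,Protocadherin-20 precursor,0.62,false,2.74,false,4.41,true,2,1,51.39
530374534,HRG,HRG,Histidine-rich glycoprotein isoform X1,0.77,true,1.04,false,1.36,false,2,49,50.77
4507725,TTHY,TTR,Transthyretin precursor,1.47,true,1.31,false,0.97,false,8,134,49.84
4885399,SMC3,SMC3,Structural maintenance of chromosomes protein 3,0.69,false,0.31,true,0.45,false,2,1,49.08
153266841,APOH,APOH,Beta-2-glycoprotein 1 precursor,1.58,true,1.75,true,1.09,false,8,124,45.16
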