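name,neutral_mass,rt,confirmation,direction,used_in_products
3-Methyladenine,149.07015,0.74,standard,increasing,GRCO;RSNP
3-Methylguanine,165.06506,1.35,standard,increasing,CHUM
5-Methylcytosine,125.05891,0.66,standard,increasing,CHUM;PINK;POL
Acetylagmatine,172.13240,0.84,standard,increasing,SQD
Acetylhistamine,153.09020,0.79,standard,increasing,YFCAN
Acetylputrescine,130.11060,0.70,standard,increasing,SQD
Acetyltyramine,179.09460,0.81,standard,increasing,YFCAN
Acetylcadaverine,144.12630,0.84,standard,increasing,CHUM;CRK;GRCO;GRNCO;MCO;POL;RSNP;SCAL;SFCO;WEAK
Choline,104.10750,0.82,standard,increasing,MCO
Creatinine,113.05890,0.61,standard,increasing,RSNP;SQD
Ethyl docosahexaenoate,356.27150,29.75,standard,increasing,CRK;MCO;POP;WEAK
Thymine,126.04290,1.66,standard,increasing,CRK;GRCO;POP;PINK;RSNP;WEAK
Tyramine,137.08410,1.40,standard,increasing,CHUM;COHO;GRCO;GRNCO;MCO;MNCO;POL;POP;RSNP;SCAL;SFCO;SFNCO;SHRP;SNP;YFCO;YFNCO
"1-(Beta-D-Ribofuranosyl)-1,4-dihydronicotinamide",256.10624,2.02,database,increasing,MNCO;POL
18-Phenyloctadecanoic acid,360.30306,30.90,database,increasing,SNP
1-Acetylpiperidine,127.09982,0.88,database,increasing,MNCO;POL
"1-Phenyl-1,3-octadecanedione",358.28741,30.28,database,increasing,CRK
2-Arachidonoylglycerol,378.27736,27.43,database,decreasing,ESCO
2-Methylbutyroylcarnitine,245.16310,6.76,database,increasing,MNCO
7-Aminomethyl-7-deazaguanine,179.08118,3.29,database,increasing,GRCO;RSNP;SQD;YFCO;YFNCO
"7Z,10Z,13Z,16Z,19Z-docosapentaenoic acid",330.25507,29.32,database,increasing,SFNCO;SHRP;YFNCO
Adenosine,267.09692,2.35,database,increasing,WEAK
Adrenic acid,332.27066,29.84,database,increasing,SFNCO;SHRP
L-2-Succinylamino-6-oxoheptanedioic acid,289.07894,2.57,database,increasing,POL
Plastoquinol-1,344.27173,29.72,database,increasing,COHO
Retinal,284.21392,29.35,database,increasing,SHRP;WEAK
Tryptophanamide,203.10642,7.44,database,increasing,YFCAN
UKN001,101.03986,3.85,unknown,increasing,COHO
UKN002,102.04785,3.85,unknown,increasing,COHO
UKN003,104.06288,3.86,unknown,increasing,COHO;SCAL;SFNCO
UKN004,113.08452,0.70,unknown,increasing,SQD
UKN005,121.08955,3.89,unknown,increasing,SQD
UKN006,122.04971,1.39,unknown,decreasing,GRNCO
UKN007,126.04360,3.66,unknown,increasing,PINK
UKN008,126.07961,0.77,unknown,increasing,SCAL;YFNCO
UKN009,143.07364,6.00,database,increasing,MNCO;SCAL;WEAK
UKN010,150.01412,5.22,unknown,increasing,COHO
UKN011,150.13678,0.60,unknown,decreasing,SCAL;SHRP
UKN012,163.08624,3.91,unknown,increasing,POL
UKN013,172.03546,0.62,unknown,increasing,PINK
UKN014,178.11101,10.68,unknown,increasing,GRCO
UKN015,182.10594,6.78,unknown,increasing,MNCO
UKN016,183.06621,25.91,unknown,decreasing,CRK
UKN017,189.02484,7.29,unknown,decreasing,WEAK
UKN018,195.07210,5.22,unknown,increasing,COHO
UKN019,199.00599,1.44,unknown,increasing,RSNP
UKN020,200.12024,29.78,unknown,increasing,SQD
UKN021,209.12797,0.83,unknown,increasing,ESCO
UKN022,210.10076,3.37,unknown,decreasing,ESCO
UKN023,214.17231,29.81,unknown,increasing,SQD
UKN024,226.13605,29.82,unknown,increasing,SQD
UKN025,230.14249,8.07,unknown,increasing,POL
UKN026,240.15155,29.82,unknown,increasing,SQD
UKN027,244.06953,0.85,unknown,increasing,POL
UKN028,250.05751,1.62,unknown,increasing,PINK
UKN029,250.10680,0.84,unknown,increasing,YFCAN
UKN030,253.24109,25.23,unknown,increasing,YFCO
UKN031,264.07308,3.66,unknown,increasing,PINK;RSNP
UKN032,274.10303,2.86,unknown,increasing,SCAL
UKN033,278.08816,1.99,unknown,increasing,SFCO
UKN034,294.05967,1.09,unknown,increasing,YFCO
UKN035,302.28228,28.26,unknown,increasing,MNCO
UKN036,306.12382,22.05,unknown,increasing,GRCO
UKN037,309.30354,28.25,unknown,increasing,SNP
UKN038,310.22934,29.75,unknown,increasing,CRK;MCO;SHRP
UKN039,312.31434,24.49,unknown,increasing,CHUM
UKN040,313.09953,0.63,unknown,increasing,POP
UKN041,317.21089,5.09,unknown,increasing,YFCAN
UKN042,321.27869,24.24,unknown,increasing,PINK
UKN043,323.31920,28.65,unknown,increasing,SNP
UKN044,325.27205,17.97,unknown,increasing,WEAK
UKN045,326.28172,32.87,unknown,decreasing,SHRP
UKN046,334.29853,23.14,unknown,increasing,CHUM
UKN047,335.99712,1.08,unknown,increasing,PINK
UKN048,336.08988,1.36,unknown,increasing,WEAK
UKN049,336.08994,1.16,unknown,increasing,SCAL;WEAK;YFCAN
UKN050,339.13353,18.04,unknown,increasing,WEAK
UKN051,340.34595,28.29,unknown,increasing,GRCO
UKN052,348.18378,30.88,unknown,increasing,YFCO
UKN053,348.18382,28.26,unknown,increasing,SOCK
UKN054,349.30961,28.12,unknown,increasing,YFNCO
UKN055,349.30974,26.05,unknown,increasing,YFCAN
UKN056,352.23723,29.33,unknown,increasing,SFNCO
UKN057,352.26123,26.66,unknown,decreasing,SFCO
UKN058,354.25377,29.82,unknown,increasing,SOCK
UKN059,357.30337,30.75,unknown,increasing,GRNCO
UKN060,357.97197,1.69,unknown,increasing,RSNP
UKN061,365.29323,27.49,unknown,increasing,CRK
UKN062,371.31917,31.61,unknown,increasing,GRNCO
UKN063,375.32459,26.47,unknown,increasing,ESCO;MCO;PINK;SOCK;YFNCO
UKN064,378.25372,29.80,unknown,increasing,SOCK
UKN065,384.19021,17.27,unknown,decreasing,SFNCO
UKN066,394.22780,29.83,unknown,increasing,SOCK
UKN067,395.29399,26.82,unknown,increasing,YFCO;YFNCO
UKN068,397.30964,27.75,unknown,increasing,YFCO;YFNCO
UKN069,398.24385,29.11,database,increasing,GRNCO
UKN070,400.29738,28.78,unknown,increasing,MCO
UKN071,401.26253,27.23,unknown,increasing,SFCO
UKN072,404.27146,28.15,unknown,decreasing,ESCO
UKN073,408.32143,29.25,unknown,increasing,SFCO
UKN074,413.13304,0.64,unknown,increasing,POP
UKN075,421.30948,27.78,unknown,increasing,YFNCO
UKN076,421.31030,25.71,unknown,increasing,PINK
UKN077,423.32527,28.61,unknown,increasing,YFNCO
UKN078,437.40976,1.80,unknown,decreasing,YFCAN
UKN079,445.30009,29.92,unknown,increasing,GRNCO
UKN080,447.31323,27.66,unknown,increasing,MCO
UKN081,531.43230,32.12,unknown,decreasing,CRK
UKN082,546.33623,29.35,unknown,decreasing,CRK
UKN083,631.28641,25.92,unknown,decreasing,CHUM
UKN084,777.53040,31.99,unknown,decreasing,CRK
UKN085,853.56261,32.72,unknown,decreasing,CRK
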