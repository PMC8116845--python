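product,common_name,n_samples,n_increments
CHUM,Chum salmon,73,7
COHO,Coho salmon,72,7
CRK,Croaker,73,7
ESCO,Escolar,73,7
GRCO,Grouper (CO),73,7
GRNCO,Grouper,71,7
MCO,Mahi mahi (CO),73,7
MNCO,Mahi mahi,73,7
PINK,Pink salmon,56,7
POL,Pollock,73,7
POP,Pacific Ocean Perch,70,7
RSNP,Red snapper,73,7
SCAL,Peruvian scallop,73,7
SFCO,Swordfish (CO),73,7
SFNCO,Swordfish,83,8
SHRP,Shrimp,73,7
SNP,Snapper,73,7
SOCK,Sockeye salmon,73,7
SQD,Squid,73,7
WEAK,Weakfish,73,7
YFCAN,Yellowfin tuna (canned),72,7
YFCO,Yellowfin tuna (CO),73,7
YFNCO,Yellowfin tuna,73,7
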