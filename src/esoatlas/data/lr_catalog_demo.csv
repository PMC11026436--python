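pair_id,ligand_subunits,receptor_subunits
IL13_IL13RA1,IL13,IL13RA1|IL4R
IL13_IL13RA2,IL13,IL13RA2
IL4_IL4R,IL4,IL4R|IL2RG
IL5_IL5RA,IL5,IL5RA|CSF2RB
IL9_IL9R,IL9,IL9R|IL2RG
IL33_IL1RL1,IL33,IL1RL1|IL1RAP
TSLP_TSLPR,TSLP,CRLF2|IL7R
CCL26_CCR3,CCL26,CCR3
CCL11_CCR3,CCL11,CCR3
CCL11_ACKR1,CCL11,ACKR1
CCL5_CCR3,CCL5,CCR3
C3_C3AR1,C3,C3AR1
IL1RN_IL1R2,IL1RN,IL1R2
IL1A_IL1R1,IL1A,IL1R1|IL1RAP
IL36A_IL1RL2,IL36A,IL1RL2|IL1RAP
TGFA_EGFR,TGFA,EGFR
AREG_EGFR,AREG,EGFR
PDGFC_PDGFRA,PDGFC,PDGFRA
FN1_ITGAV,FN1,ITGAV|ITGB1
VCAN_CD44,VCAN,CD44
MADCAM1_ITGA4B7,MADCAM1,ITGA4|ITGB7
VCAM1_ITGA4B1,VCAM1,ITGA4|ITGB1
ICAM1_ITGAL,ICAM1,ITGAL|ITGB2
SELP_SELPLG,SELP,SELPLG
LIF_LIFR,LIF,LIFR|IL6ST
KITLG_KIT,KITLG,KIT
IGF2_IGF1R,IGF2,IGF1R
GAS6_AXL,GAS6,AXL
CXCL12_CXCR4,CXCL12,CXCR4
TGFB1_TGFBR,TGFB1,TGFBR1|TGFBR2
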