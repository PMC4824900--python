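# Bacterial single-copy-gene collection (139 genes).
# One Pfam-style domain identifier per line; lines starting with '#' are
# ignored. These are the protein families screened once-per-genome in
# nearly all bacteria (ribosomal proteins, aminoacyl-tRNA synthetases,
# RNA polymerase subunits, core replication/translation machinery).
Ribosom_S12_S23
Ribosomal_L1
Ribosomal_L2
Ribosomal_L2_C
Ribosomal_L3
Ribosomal_L4
Ribosomal_L5
Ribosomal_L5_C
Ribosomal_L6
Ribosomal_L9_C
Ribosomal_L9_N
Ribosomal_L10
Ribosomal_L11
Ribosomal_L11_N
Ribosomal_L12
Ribosomal_L13
Ribosomal_L14
Ribosomal_L16
Ribosomal_L17
Ribosomal_L18p
Ribosomal_L19
Ribosomal_L20
Ribosomal_L21p
Ribosomal_L22
Ribosomal_L23
Ribosomal_L25p
Ribosomal_L27
Ribosomal_L28
Ribosomal_L29
Ribosomal_L30
Ribosomal_L32p
Ribosomal_L33
Ribosomal_L34
Ribosomal_L35p
Ribosomal_L36
Ribosomal_S2
Ribosomal_S3_C
Ribosomal_S4
Ribosomal_S5
Ribosomal_S5_C
Ribosomal_S6
Ribosomal_S7
Ribosomal_S8
Ribosomal_S9
Ribosomal_S10
Ribosomal_S11
Ribosomal_S13
Ribosomal_S14
Ribosomal_S15
Ribosomal_S16
Ribosomal_S17
Ribosomal_S18
Ribosomal_S19
Ribosomal_S20p
tRNA-synt_1
tRNA-synt_1b
tRNA-synt_1c
tRNA-synt_1c_C
tRNA-synt_1d
tRNA-synt_1e
tRNA-synt_1f
tRNA-synt_1g
tRNA-synt_2
tRNA-synt_2b
tRNA-synt_2c
tRNA-synt_2d
tRNA-synt_His
GTP_EFTU
GTP_EFTU_D2
GTP_EFTU_D3
EF_TS
EFG_C
EFG_IV
EFP
IF-2
IF2_N
IF3_C
IF3_N
PCRF
RF-1
RRF
SmpB
Pept_tRNA_hydro
GTP1_OBG
MMR_HSR1
RNA_pol_A_bac
RNA_pol_A_CTD
RNA_pol_L
RNA_pol_Rpb1_1
RNA_pol_Rpb1_2
RNA_pol_Rpb1_3
RNA_pol_Rpb1_4
RNA_pol_Rpb1_5
RNA_pol_Rpb2_1
RNA_pol_Rpb2_2
RNA_pol_Rpb2_3
RNA_pol_Rpb2_45
RNA_pol_Rpb2_6
RNA_pol_Rpb2_7
Sigma70_r1_2
Sigma70_r2
Sigma70_r3
Sigma70_r4
NusA_N
NusB
KOW
Bac_DnaA
DNA_pol3_beta
DNA_pol3_beta_2
DNA_pol3_beta_3
DnaB
DnaB_C
DNA_gyraseB
DNA_gyraseB_C
Toprim_N
RecA
RecR
RuvA_N
RuvB_N
RuvC
SSB
UvrB
Trigger_C
Trigger_N
GrpE
DnaJ
DnaJ_CXXCXGXG
SecE
SecG
SecY
SRP54
SRP_SPB
RimM
RBFA
TruB_N
tRNA_m1G_MT
PseudoU_synth_1
Methyltransf_5
UPF0054
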