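# Reference retention times for the 21 commercially available synthetic AHL standards.
# source=table: Rt as printed in the study's identification tables (median across tables).
# source=model: SYNTHETIC value predicted by the package's retention-time model,
#               not measured data (no published Rt exists for these standards).
name,chain_length,unsat,subst,reference_rt_min,source
C4-AHL,4,0,plain,6.97,model
C6-AHL,6,0,plain,11.86,table
OC6-AHL,6,0,3-oxo,7.72,model
C8-AHL,8,0,plain,15.39,table
OC8-AHL,8,0,3-oxo,11.52,model
OHC8-AHL,8,0,3-hydroxy,10.46,table
C10-AHL,10,0,plain,23.73,model
OC10-AHL,10,0,3-oxo,17.45,table
OHC10-AHL,10,0,3-hydroxy,16.17,table
C12-AHL,12,0,plain,24.18,table
OC12-AHL,12,0,3-oxo,23.73,model
OHC12-AHL,12,0,3-hydroxy,20.08,table
C14-AHL,14,0,plain,27.63,table
OC14-AHL,14,0,3-oxo,24.96,table
OHC14-AHL,14,0,3-hydroxy,23.58,table
C16-AHL,16,0,plain,30.71,table
OC16-AHL,16,0,3-oxo,25.22,table
OHC16-AHL,16,0,3-hydroxy,25.18,table
C18-AHL,18,0,plain,33.88,table
OC18-AHL,18,0,3-oxo,31.26,table
OHC18-AHL,18,0,3-hydroxy,30.25,table
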