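dimension,specimen_mm,specimen_sd_mm,model_mm,model_delta_mm,skin_mm
distal_phalanx_length,19.67,1.03,19.10,0.57,30.65
middle_phalanx_length,24.67,0.98,25.10,0.43,27.22
proximal_phalanx_length,43.57,0.98,42.60,0.97,50.86
DIP_joint_thickness,5.58,0.92,4.95,0.63,14.38
PIP_joint_thickness,7.57,0.45,7.31,0.26,18.86
MCP_joint_thickness,15.57,0.84,17.08,1.51,27.80
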