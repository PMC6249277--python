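kind,label,x_deg,y_deg,start_deg,end_deg
disc,temporal,,,315,45
disc,temporal_superior,,,45,90
disc,nasal_superior,,,90,135
disc,nasal,,,135,225
disc,nasal_inferior,,,225,270
disc,temporal_inferior,,,270,315
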