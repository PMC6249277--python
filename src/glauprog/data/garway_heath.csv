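kind,label,x_deg,y_deg,start_deg,end_deg
vf,nasal_superior,-9,21,,
vf,nasal_superior,-3,21,,
vf,temporal_superior,3,21,,
vf,temporal_superior,9,21,,
vf,nasal_superior,-15,15,,
vf,nasal_superior,-9,15,,
vf,nasal_superior,-3,15,,
vf,nasal_superior,3,15,,
vf,temporal_superior,9,15,,
vf,temporal_superior,15,15,,
vf,nasal_superior,-21,9,,
vf,nasal_superior,-15,9,,
vf,nasal_superior,-9,9,,
vf,nasal_superior,-3,9,,
vf,nasal_superior,3,9,,
vf,nasal_superior,9,9,,
vf,temporal_superior,15,9,,
vf,temporal,21,9,,
vf,nasal_superior,-27,3,,
vf,nasal_superior,-21,3,,
vf,nasal_superior,-15,3,,
vf,nasal_superior,-9,3,,
vf,central,-3,3,,
vf,central,3,3,,
vf,central,9,3,,
vf,temporal,21,3,,
vf,nasal_inferior,-27,-3,,
vf,nasal_inferior,-21,-3,,
vf,nasal_inferior,-15,-3,,
vf,nasal_inferior,-9,-3,,
vf,central,-3,-3,,
vf,central,3,-3,,
vf,central,9,-3,,
vf,temporal,21,-3,,
vf,nasal_inferior,-21,-9,,
vf,nasal_inferior,-15,-9,,
vf,nasal_inferior,-9,-9,,
vf,nasal_inferior,-3,-9,,
vf,nasal_inferior,3,-9,,
vf,nasal_inferior,9,-9,,
vf,temporal_inferior,15,-9,,
vf,temporal,21,-9,,
vf,nasal_inferior,-15,-15,,
vf,nasal_inferior,-9,-15,,
vf,nasal_inferior,-3,-15,,
vf,nasal_inferior,3,-15,,
vf,temporal_inferior,9,-15,,
vf,temporal_inferior,15,-15,,
vf,nasal_inferior,-9,-21,,
vf,nasal_inferior,-3,-21,,
vf,temporal_inferior,3,-21,,
vf,temporal_inferior,9,-21,,
disc,temporal,,,311,40
disc,temporal_superior,,,40,80
disc,nasal_superior,,,80,120
disc,nasal,,,120,230
disc,nasal_inferior,,,230,270
disc,temporal_inferior,,,270,311
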