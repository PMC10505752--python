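group,species,entity,n_tumors,n_diffuse_positive,n_tn_gt10,n_tn_evaluable,n_overexpressing,percent_overexpressing
human_total,human,all,39,32,18,34,33,85
MPNST,human,MPNST,10,7,3,9,7,90
UPS,human,UPS,10,9,7,10,9,90
DFSP,human,DFSP,9,7,3,7,7,78
MFS,human,MFS,10,9,5,8,9,90
canine_total,canine,all,53,30,20,44,40,76
PWT,canine,PWT,30,22,12,23,25,83
STS_NOS,canine,STS_NOS,16,5,5,14,10,62
cFS,canine,cFS,7,3,3,7,5,71
fFS,feline,fFS,24,19,11,22,22,92
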