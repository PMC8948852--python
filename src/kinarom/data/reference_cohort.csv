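id,group,chronological_age,mental_age,macs,gmfcs,fma_total
cg-01,control,4,4,,,65
cg-02,control,4,4,,,64
cg-03,control,5,5,,,65
cg-04,control,5,5,,,66
cg-05,control,5,5,,,66
cg-06,control,6,6,,,65
cg-07,control,7,7,,,64
cg-08,control,8,8,,,66
cg-09,control,8,8,,,66
cg-10,control,8,8,,,66
cg-11,control,9,9,,,63
cg-12,control,9,9,,,63
cg-13,control,9,9,,,63
cg-14,control,9,9,,,63
cg-15,control,11,11,,,66
cg-16,control,11,11,,,66
cg-17,control,11,11,,,66
cg-18,control,12,12,,,66
sg-01,study,4,-,I,II,57
sg-02,study,5,4,II,II,60
sg-03,study,5,4,I,II,54
sg-04,study,6,4,II,II,50
sg-05,study,6,6,I,I,63
sg-06,study,8,6,I,I,65
sg-07,study,8,5,II,II,39
sg-08,study,8,7,II,I,64
sg-09,study,9,5,II,II,52
sg-10,study,9,-,I,II,53
sg-11,study,9,7,I,II,57
sg-12,study,9,5,II,II,42
sg-13,study,9,8,I,I,65
sg-14,study,9,4,I,I,65
sg-15,study,10,5,I,I,62
sg-16,study,11,7,I,II,66
sg-17,study,12,8,II,I,31
sg-18,study,12,9,II,I,58
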