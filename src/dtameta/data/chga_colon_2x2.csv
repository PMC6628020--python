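study_id,TP,FP,FN,TN
GSE44076 (1),92,1,6,49
GSE44076 (2),87,5,10,93
GSE74602,25,5,6,24
GSE10972,21,10,3,14
GSE23878,30,3,5,21
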