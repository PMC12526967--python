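subject,paradigm,classifier,window_s,accuracy_pct
S1,ARROW,LDA,2,73
S1,ARROW,SVM_LINEAR,2,75.37
S1,ARROW,SVM_POLY3,2,70.75
S1,PICTURE,LDA,2,82.25
S1,PICTURE,SVM_LINEAR,2,81.38
S1,PICTURE,SVM_POLY3,2,82.38
S1,VIDEO,LDA,2,81.75
S1,VIDEO,SVM_LINEAR,2,82
S1,VIDEO,SVM_POLY3,2,84.25
S2,ARROW,LDA,2,62.87
S2,ARROW,SVM_LINEAR,2,63.25
S2,ARROW,SVM_POLY3,2,62.38
S2,PICTURE,LDA,2,68.5
S2,PICTURE,SVM_LINEAR,2,66.75
S2,PICTURE,SVM_POLY3,2,70.13
S2,VIDEO,LDA,2,68
S2,VIDEO,SVM_LINEAR,2,69.38
S2,VIDEO,SVM_POLY3,2,60.13
S3,ARROW,LDA,2,67
S3,ARROW,SVM_LINEAR,2,66.75
S3,ARROW,SVM_POLY3,2,66.13
S3,PICTURE,LDA,2,69.38
S3,PICTURE,SVM_LINEAR,2,65.25
S3,PICTURE,SVM_POLY3,2,64.75
S3,VIDEO,LDA,2,70.12
S3,VIDEO,SVM_LINEAR,2,70.5
S3,VIDEO,SVM_POLY3,2,68.38
S4,ARROW,LDA,2,63.88
S4,ARROW,SVM_LINEAR,2,64.25
S4,ARROW,SVM_POLY3,2,60.38
S4,PICTURE,LDA,2,66.13
S4,PICTURE,SVM_LINEAR,2,66.62
S4,PICTURE,SVM_POLY3,2,66.5
S4,VIDEO,LDA,2,64.25
S4,VIDEO,SVM_LINEAR,2,65.25
S4,VIDEO,SVM_POLY3,2,61.63
S5,ARROW,LDA,2,73
S5,ARROW,SVM_LINEAR,2,71.38
S5,ARROW,SVM_POLY3,2,73.13
S5,PICTURE,LDA,2,74.88
S5,PICTURE,SVM_LINEAR,2,74.88
S5,PICTURE,SVM_POLY3,2,74.37
S5,VIDEO,LDA,2,63.13
S5,VIDEO,SVM_LINEAR,2,61
S5,VIDEO,SVM_POLY3,2,63.38
S6,ARROW,LDA,2,65
S6,ARROW,SVM_LINEAR,2,65.63
S6,ARROW,SVM_POLY3,2,61.88
S6,PICTURE,LDA,2,73.5
S6,PICTURE,SVM_LINEAR,2,71
S6,PICTURE,SVM_POLY3,2,71.25
S6,VIDEO,LDA,2,64.5
S6,VIDEO,SVM_LINEAR,2,66
S6,VIDEO,SVM_POLY3,2,70
S7,ARROW,LDA,2,68.63
S7,ARROW,SVM_LINEAR,2,69.75
S7,ARROW,SVM_POLY3,2,70
S7,PICTURE,LDA,2,84
S7,PICTURE,SVM_LINEAR,2,84.25
S7,PICTURE,SVM_POLY3,2,89.13
S7,VIDEO,LDA,2,91.38
S7,VIDEO,SVM_LINEAR,2,92.13
S7,VIDEO,SVM_POLY3,2,93.5
S8,ARROW,LDA,2,62
S8,ARROW,SVM_LINEAR,2,61.25
S8,ARROW,SVM_POLY3,2,62.25
S8,PICTURE,LDA,2,72.63
S8,PICTURE,SVM_LINEAR,2,71.63
S8,PICTURE,SVM_POLY3,2,73.75
S8,VIDEO,LDA,2,64.87
S8,VIDEO,SVM_LINEAR,2,65.25
S8,VIDEO,SVM_POLY3,2,62.87
S9,ARROW,LDA,2,69.5
S9,ARROW,SVM_LINEAR,2,69.75
S9,ARROW,SVM_POLY3,2,69.38
S9,PICTURE,LDA,2,74.88
S9,PICTURE,SVM_LINEAR,2,73.75
S9,PICTURE,SVM_POLY3,2,77.5
S9,VIDEO,LDA,2,80.25
S9,VIDEO,SVM_LINEAR,2,78.75
S9,VIDEO,SVM_POLY3,2,77.75
S10,ARROW,LDA,2,74.37
S10,ARROW,SVM_LINEAR,2,74.13
S10,ARROW,SVM_POLY3,2,72.5
S10,PICTURE,LDA,2,97.5
S10,PICTURE,SVM_LINEAR,2,96.25
S10,PICTURE,SVM_POLY3,2,96.38
S10,VIDEO,LDA,2,96.62
S10,VIDEO,SVM_LINEAR,2,96.25
S10,VIDEO,SVM_POLY3,2,95
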