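subject,paradigm,classifier,window_s,accuracy_pct
S1,ARROW,LDA,2,73.62
S1,ARROW,SVM_LINEAR,2,75.25
S1,ARROW,SVM_POLY3,2,72.25
S1,ARROW,LDA,3,75.87
S1,ARROW,SVM_LINEAR,3,74.5
S1,ARROW,SVM_POLY3,3,74.62
S1,PICTURE,LDA,2,81.12
S1,PICTURE,SVM_LINEAR,2,80.5
S1,PICTURE,SVM_POLY3,2,81.75
S1,PICTURE,LDA,3,76.75
S1,PICTURE,SVM_LINEAR,3,79.87
S1,PICTURE,SVM_POLY3,3,79.25
S1,VIDEO,LDA,2,81.63
S1,VIDEO,SVM_LINEAR,2,83.25
S1,VIDEO,SVM_POLY3,2,82.75
S1,VIDEO,LDA,3,81.13
S1,VIDEO,SVM_LINEAR,3,81.63
S1,VIDEO,SVM_POLY3,3,83.13
S2,ARROW,LDA,2,75.87
S2,ARROW,SVM_LINEAR,2,62.75
S2,ARROW,SVM_POLY3,2,64.25
S2,ARROW,LDA,3,63.12
S2,ARROW,SVM_LINEAR,3,65.12
S2,ARROW,SVM_POLY3,3,63.5
S2,PICTURE,LDA,2,62.88
S2,PICTURE,SVM_LINEAR,2,63.87
S2,PICTURE,SVM_POLY3,2,66.87
S2,PICTURE,LDA,3,65.38
S2,PICTURE,SVM_LINEAR,3,64.5
S2,PICTURE,SVM_POLY3,3,64.5
S2,VIDEO,LDA,2,65.5
S2,VIDEO,SVM_LINEAR,2,63.5
S2,VIDEO,SVM_POLY3,2,59.5
S2,VIDEO,LDA,3,62.62
S2,VIDEO,SVM_LINEAR,3,63.5
S2,VIDEO,SVM_POLY3,3,62.25
S3,ARROW,LDA,2,65.87
S3,ARROW,SVM_LINEAR,2,65.63
S3,ARROW,SVM_POLY3,2,63
S3,ARROW,LDA,3,62.12
S3,ARROW,SVM_LINEAR,3,61.5
S3,ARROW,SVM_POLY3,3,63.5
S3,PICTURE,LDA,2,69.37
S3,PICTURE,SVM_LINEAR,2,69.63
S3,PICTURE,SVM_POLY3,2,69.38
S3,PICTURE,LDA,3,70.87
S3,PICTURE,SVM_LINEAR,3,69.87
S3,PICTURE,SVM_POLY3,3,71.63
S3,VIDEO,LDA,2,70.63
S3,VIDEO,SVM_LINEAR,2,71.88
S3,VIDEO,SVM_POLY3,2,70.5
S3,VIDEO,LDA,3,72.25
S3,VIDEO,SVM_LINEAR,3,72.5
S3,VIDEO,SVM_POLY3,3,69.5
S4,ARROW,LDA,2,66.75
S4,ARROW,SVM_LINEAR,2,64.62
S4,ARROW,SVM_POLY3,2,63
S4,ARROW,LDA,3,64.75
S4,ARROW,SVM_LINEAR,3,64
S4,ARROW,SVM_POLY3,3,63.75
S4,PICTURE,LDA,2,67.87
S4,PICTURE,SVM_LINEAR,2,66.75
S4,PICTURE,SVM_POLY3,2,63.5
S4,PICTURE,LDA,3,65.63
S4,PICTURE,SVM_LINEAR,3,66
S4,PICTURE,SVM_POLY3,3,66.37
S4,VIDEO,LDA,2,63.88
S4,VIDEO,SVM_LINEAR,2,62.62
S4,VIDEO,SVM_POLY3,2,60.25
S4,VIDEO,LDA,3,59.63
S4,VIDEO,SVM_LINEAR,3,59.88
S4,VIDEO,SVM_POLY3,3,54.87
S5,ARROW,LDA,2,67.87
S5,ARROW,SVM_LINEAR,2,67.88
S5,ARROW,SVM_POLY3,2,67.88
S5,ARROW,LDA,3,68
S5,ARROW,SVM_LINEAR,3,69.12
S5,ARROW,SVM_POLY3,3,69.12
S5,PICTURE,LDA,2,73.13
S5,PICTURE,SVM_LINEAR,2,74.25
S5,PICTURE,SVM_POLY3,2,71.88
S5,PICTURE,LDA,3,67.88
S5,PICTURE,SVM_LINEAR,3,70.63
S5,PICTURE,SVM_POLY3,3,67.13
S5,VIDEO,LDA,2,60.75
S5,VIDEO,SVM_LINEAR,2,58.5
S5,VIDEO,SVM_POLY3,2,60.13
S5,VIDEO,LDA,3,58.13
S5,VIDEO,SVM_LINEAR,3,58.5
S5,VIDEO,SVM_POLY3,3,62.38
S6,ARROW,LDA,2,64.62
S6,ARROW,SVM_LINEAR,2,63
S6,ARROW,SVM_POLY3,2,61.75
S6,ARROW,LDA,3,65.37
S6,ARROW,SVM_LINEAR,3,64.12
S6,ARROW,SVM_POLY3,3,60.5
S6,PICTURE,LDA,2,73.75
S6,PICTURE,SVM_LINEAR,2,71.37
S6,PICTURE,SVM_POLY3,2,71.37
S6,PICTURE,LDA,3,71.63
S6,PICTURE,SVM_LINEAR,3,71.88
S6,PICTURE,SVM_POLY3,3,70.38
S6,VIDEO,LDA,2,63.88
S6,VIDEO,SVM_LINEAR,2,60.5
S6,VIDEO,SVM_POLY3,2,66.63
S6,VIDEO,LDA,3,63.88
S6,VIDEO,SVM_LINEAR,3,60.5
S6,VIDEO,SVM_POLY3,3,62.62
S7,ARROW,LDA,2,68.37
S7,ARROW,SVM_LINEAR,2,68.87
S7,ARROW,SVM_POLY3,2,69
S7,ARROW,LDA,3,67.37
S7,ARROW,SVM_LINEAR,3,69.12
S7,ARROW,SVM_POLY3,3,67.12
S7,PICTURE,LDA,2,83.13
S7,PICTURE,SVM_LINEAR,2,84.38
S7,PICTURE,SVM_POLY3,2,86.5
S7,PICTURE,LDA,3,86.12
S7,PICTURE,SVM_LINEAR,3,84.88
S7,PICTURE,SVM_POLY3,3,84.38
S7,VIDEO,LDA,2,90.5
S7,VIDEO,SVM_LINEAR,2,90.88
S7,VIDEO,SVM_POLY3,2,92.5
S7,VIDEO,LDA,3,87
S7,VIDEO,SVM_LINEAR,3,87.63
S7,VIDEO,SVM_POLY3,3,87.38
S8,ARROW,LDA,2,61.38
S8,ARROW,SVM_LINEAR,2,62.13
S8,ARROW,SVM_POLY3,2,62.13
S8,ARROW,LDA,3,65.37
S8,ARROW,SVM_LINEAR,3,58
S8,ARROW,SVM_POLY3,3,59.62
S8,PICTURE,LDA,2,71.88
S8,PICTURE,SVM_LINEAR,2,72.13
S8,PICTURE,SVM_POLY3,2,71.75
S8,PICTURE,LDA,3,71.62
S8,PICTURE,SVM_LINEAR,3,69.25
S8,PICTURE,SVM_POLY3,3,70.12
S8,VIDEO,LDA,2,60.75
S8,VIDEO,SVM_LINEAR,2,61.12
S8,VIDEO,SVM_POLY3,2,62
S8,VIDEO,LDA,3,72.12
S8,VIDEO,SVM_LINEAR,3,61.12
S8,VIDEO,SVM_POLY3,3,66.38
S9,ARROW,LDA,2,66.13
S9,ARROW,SVM_LINEAR,2,62.25
S9,ARROW,SVM_POLY3,2,63.25
S9,ARROW,LDA,3,70.63
S9,ARROW,SVM_LINEAR,3,72
S9,ARROW,SVM_POLY3,3,65.38
S9,PICTURE,LDA,2,73.37
S9,PICTURE,SVM_LINEAR,2,71.37
S9,PICTURE,SVM_POLY3,2,73.38
S9,PICTURE,LDA,3,71.75
S9,PICTURE,SVM_LINEAR,3,69.87
S9,PICTURE,SVM_POLY3,3,69.5
S9,VIDEO,LDA,2,81.25
S9,VIDEO,SVM_LINEAR,2,71.62
S9,VIDEO,SVM_POLY3,2,68.63
S9,VIDEO,LDA,3,77.13
S9,VIDEO,SVM_LINEAR,3,79.38
S9,VIDEO,SVM_POLY3,3,76.63
S10,ARROW,LDA,2,77
S10,ARROW,SVM_LINEAR,2,76.37
S10,ARROW,SVM_POLY3,2,75.5
S10,ARROW,LDA,3,69.5
S10,ARROW,SVM_LINEAR,3,70.75
S10,ARROW,SVM_POLY3,3,71.12
S10,PICTURE,LDA,2,96.62
S10,PICTURE,SVM_LINEAR,2,95.87
S10,PICTURE,SVM_POLY3,2,96.38
S10,PICTURE,LDA,3,88.38
S10,PICTURE,SVM_LINEAR,3,89.75
S10,PICTURE,SVM_POLY3,3,88
S10,VIDEO,LDA,2,96
S10,VIDEO,SVM_LINEAR,2,96.38
S10,VIDEO,SVM_POLY3,2,95
S10,VIDEO,LDA,3,93.62
S10,VIDEO,SVM_LINEAR,3,93.75
S10,VIDEO,SVM_POLY3,3,93.75
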