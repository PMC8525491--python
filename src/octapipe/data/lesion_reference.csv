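condition,day,dimension,mean_um,cv
acute,1,onl,128.31,0.10
acute,1,rpe,136.59,0.16
acute,1,height,121.39,0.06
acute,1,pr,129.71,0.08
acute,3,onl,110.90,0.22
acute,3,rpe,196.09,0.23
acute,3,height,131.55,0.08
acute,3,pr,78.07,0.18
acute,7,onl,87.86,0.36
acute,7,rpe,156.98,0.19
acute,7,height,125.08,0.10
acute,7,pr,60.96,0.20
acute,14,onl,94.38,0.32
acute,14,rpe,146.75,0.31
acute,14,height,123.95,0.11
acute,14,pr,64.52,0.25
acute,21,onl,94.50,0.28
acute,21,rpe,137.17,0.33
acute,21,height,121.55,0.08
acute,21,pr,69.13,0.24
cnv,1,onl,408.75,0.24
cnv,1,rpe,345.66,0.50
cnv,1,height,170.38,0.19
cnv,1,pr,276.72,0.43
cnv,3,onl,418.96,0.24
cnv,3,rpe,428.85,0.13
cnv,3,height,204.83,0.19
cnv,3,pr,278.93,0.25
cnv,7,onl,566.08,0.34
cnv,7,rpe,566.49,0.32
cnv,7,height,246.35,0.32
cnv,7,pr,401.73,0.50
cnv,14,onl,457.69,0.39
cnv,14,rpe,520.06,0.30
cnv,14,height,197.74,0.29
cnv,14,pr,314.71,0.49
cnv,21,onl,433.87,0.43
cnv,21,rpe,528.33,0.37
cnv,21,height,178.06,0.26
cnv,21,pr,342.27,0.52
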