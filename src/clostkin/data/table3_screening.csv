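sample_id,group,colony_number,r_butyric,r_butyric_sd,r_acetic,r_acetic_sd,printed_delta
W,wild-type,,34.32,0.13,11.24,0.09,3.05
QSH-M-F75-1-1,QSH-M-F75-1,9,43.56,0.19,10.37,0.23,3.43
QSH-M-F75-1-2,QSH-M-F75-1,9,47.86,0.12,9.78,0.17,4.98
QSH-M-F75-2-1,QSH-M-F75-2,15,44.46,0.15,10.17,0.21,4.37
QSH-M-F75-2-2,QSH-M-F75-2,15,39.78,0.23,9.64,0.12,4.13
QSH-M-F75-3-1,QSH-M-F75-3,19,40.78,0.11,12.56,0.17,3.25
QSH-M-F75-3-2,QSH-M-F75-3,19,36.35,0.21,12.78,0.06,2.85
QSH-M-F75-4-1,QSH-M-F75-4,17,31.67,0.23,13.42,0.09,2.36
QSH-M-F75-4-2,QSH-M-F75-4,17,35.36,0.32,11.87,0.21,2.98
QSH-M-F75-5-1,QSH-M-F75-5,8,51.18,0.16,10.27,0.11,4.98
QSH-M-F75-5-2,QSH-M-F75-5,8,49.65,0.23,9.62,0.12,5.16
QSH-M-F75-6-1,QSH-M-F75-6,23,58.93,0.27,10.78,0.13,5.45
QSH-M-F75-6-2,QSH-M-F75-6,23,49.36,0.21,9.92,0.19,4.98
QSH-M-F75-7-1,QSH-M-F75-7,9,33.75,0.13,12.35,0.27,2.73
QSH-M-F75-7-2,QSH-M-F75-7,9,35.63,0.09,11.21,0.17,3.18
QSH-M-F75-8-1,QSH-M-F75-8,328,53.36,0.18,11.36,0.09,4.70
QSH-M-F75-8-2,QSH-M-F75-8,328,35.67,0.24,12.31,0.18,2.90
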