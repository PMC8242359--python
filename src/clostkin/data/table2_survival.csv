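sample_id,dose_gy,n_total,n_lethal,printed_survival_prop
Q36-8,50,5900,900,0.8475
Q36-8,55,6250,2470,0.6048
Q36-8,60,5500,2940,0.4655
Q36-8,65,5600,3250,0.4196
Q36-8,70,6300,5170,0.1794
Q36-8,75,5900,5300,0.1017
Q36-8,80,6200,6200,0
S24-3,50,6100,740,0.8787
S24-3,55,6000,2300,0.6167
S24-3,60,5900,3150,0.4661
S24-3,65,5600,3270,0.4161
S24-3,70,6300,5200,0.1746
S24-3,75,6200,5490,0.1145
S24-3,80,6100,6100,0
H51-8,50,6200,730,0.8823
H51-8,55,5500,2070,0.6236
H51-8,60,6200,3200,0.4839
H51-8,65,5600,3100,0.4464
H51-8,70,5500,4560,0.1709
H51-8,75,6300,5600,0.1111
H51-8,80,5600,5600,0
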