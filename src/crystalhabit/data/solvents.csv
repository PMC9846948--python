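name,relative_permittivity,dipole_moment,density,n_carbon
MeCN,37.5,3.92,0.786,2
ace,20.7,2.88,0.784,3
NMP,32.2,4.09,1.028,5
DMSO,46.7,3.96,1.100,2
MEF,111.0,3.73,1.133,1
DMF,36.7,3.82,0.944,3
DMAC,37.8,3.72,0.937,4
DEF,28.4,3.62,0.908,5
DEAC,31.3,3.72,0.913,6
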