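# Recommended OH rate constants at 298 K, cm^3 molecule^-1 s^-1.
# Values follow the IUPAC / Atkinson & Arey kinetics evaluations.
species,k_oh,source
isoprene,1.0e-10,IUPAC recommendation (298 K)
alpha-pinene,5.3e-11,Atkinson & Arey 2003
beta-pinene,7.9e-11,Atkinson & Arey 2003
limonene,1.7e-10,Atkinson & Arey 2003
methanol,9.4e-13,IUPAC recommendation (298 K)
dms,6.5e-12,IUPAC recommendation (298 K; OH addition + abstraction)
m-xylene,2.3e-11,Atkinson & Arey 2003
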