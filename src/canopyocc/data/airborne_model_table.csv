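model,elev,fhd,hli,hmode,hmrange,hskew,hvar,p_mid,wind,df,logLik,AICc,delta,weight
384,70.50,115.97,27.05,-66.44,82.84,83.16,-54.48,,-0.25,10,-79.57,182.24,0.00,0.44
512,78.33,113.98,30.32,-63.20,92.53,92.54,-53.74,17.49,-0.25,11,-79.47,184.70,2.47,0.13
448,73.00,90.95,24.19,-49.88,55.74,111.96,,23.54,-0.30,10,-81.13,185.35,3.12,0.09
120,21.96,107.30,65.65,,73.64,88.37,-21.12,,,8,-84.19,186.36,4.12,0.06
188,108.37,193.01,,-73.42,140.18,327.12,,64.45,,8,-84.34,186.66,4.42,0.05
7,,-28.76,153.00,,,,,,,4,-89.12,186.76,4.52,0.05
63,,339.22,196.97,37.61,145.38,371.68,,,,7,-85.96,187.43,5.20,0.03
263,,-34.82,186.06,,,,,,-0.19,5,-88.53,187.84,5.61,0.03
56,34.05,170.41,111.76,,106.84,144.86,,,,7,-86.22,187.96,5.72,0.03
135,,-29.03,133.33,,,,,5.20,,5,-88.60,187.99,5.76,0.02
37,,,142.39,,,33.49,,,,4,-89.76,188.04,5.81,0.02
149,,,95.41,,-54.03,,,-58.84,,5,-88.64,188.08,5.84,0.02
124,63.46,76.63,,-51.78,63.56,51.64,-34.86,,,8,-85.08,188.13,5.89,0.02
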