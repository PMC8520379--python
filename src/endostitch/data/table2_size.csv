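max_diameter_cm,hyperplastic,inflammatory,fundic_gland,metaplastic,hamartoma,adenomatous,gastric_cancer
<=0.5,36,33,5,1,0,2,0
0.5-2.0,6,4,1,0,0,0,1
>=2.0,3,0,0,1,1,2,15
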