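age,hyperplastic,inflammatory,fundic_gland,metaplastic,hamartoma,adenomatous,gastric_cancer
<=44,10,4,0,1,0,0,2
44-60,9,14,2,1,1,0,4
>=60,26,19,4,0,0,4,10
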