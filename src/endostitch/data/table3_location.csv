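location,hyperplastic,inflammatory,fundic_gland,metaplastic,hamartoma,adenomatous,gastric_cancer
stomach_body,21,17,4,1,1,4,10
antrum,12,13,0,1,0,0,2
fundus,9,5,2,0,0,0,0
cardia,0,1,0,0,0,0,4
stomach_angle,2,0,0,0,0,0,0
multi_site,1,1,0,0,0,0,0
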