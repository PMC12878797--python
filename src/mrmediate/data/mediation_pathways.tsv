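exposure	mediator	outcome_id	beta_all	beta_mediation	reported_ratio
Alpha-hydroxyisovalerate levels	IL-8	ieu-b-4961	0.000196642	4.71e-05	0.118774978
5alpha-androstan-3beta,17alpha-diol disulfate levels	IL-8	ieu-b-4961	-0.000419579	-7.01e-05	0.159581059
Pregnenediol sulfate (C21H14O5S) levels	EN-RAGE	ieu-b-4961	0.000515012	4.41e-05	0.082726129
2-Piperidinone levels	CXCL1	ieu-b-4961	-0.000724944	-5.01e-05	0.069126711
1-Stearoyl-2-oleoyl-gpc (18:0/18:1) levels	IL-15RA	ieu-b-4961	-0.000711512	-6.10e-05	0.085902944
Myristoyl dihydrosphingomyelin (d18:0/14:0) levels	CD40	ieu-b-4961	0.000544956	1.48e-05	0.027124781
Myristoyl dihydrosphingomyelin (d18:0/14:0) levels	IL-8	ieu-b-4961	0.000544956	8.46e-05	0.155278707
(S)-1-Hydroxybutyrylcarnitine levels	CXCL1	ieu-b-4961	-0.00049044	-4.49e-05	0.091504112
Ascorbic acid 2-sulfate levels	AXIN1	ieu-b-4961	0.000741968	7.64e-05	0.102641551
Carotene diol (1) levels	TRANCE	ieu-b-4961	0.000500512	1.15e-05	0.026970684
Aspartate levels	CCL11	ieu-b-4961	-0.000529911	-6.42e-05	0.121124029
Trans-urocanate levels	AXIN1	ieu-b-4961	0.000489279	8.52e-05	0.174096742
X-18921 levels	AXIN1	ieu-b-4961	0.000195602	5.07e-05	0.128150429
Cysteine-to-5-oxoproline ratio	TRANCE	ieu-b-4961	0.000171078	1.27e-05	0.014026091
Retinol (vitamin A)-to-oleoyl-linoleoyl-glycerol (18:1-18:2) [2] ratio	IL-15RA	ieu-b-4961	0.000497657	1.51e-05	0.070926812
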