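genus	species	category	specimen	pd	syn_per_kb	nonsyn_fraction	nonsense_fraction	provean_fraction	sift_fraction
Ajuga	A. boninsimae	EIE	100PE	0.705	0.027	0.723	0.048	0.495	0.434
Ajuga	A. boninsimae	EIE	150PE-1	0.721	0.019	0.670	0.036	0.470	0.383
Ajuga	A. boninsimae	EIE	150PE-2	0.696	0.022	0.669	0.052	0.444	0.359
Ajuga	A. boninsimae	EIE	150PE-3	0.716	0.023	0.662	0.046	0.465	0.349
Ajuga	A. boninsimae	EIE	150PE-4	0.713	0.021	0.662	0.033	0.422	0.325
Ajuga	A. pygmaea	NE	100PE	0.715	0.025	0.699	0.040	0.464	0.389
Ajuga	A. pygmaea	NE	150PE-1	0.715	0.030	0.597	0.035	0.437	0.352
Ajuga	A. pygmaea	NE	150PE-2	0.730	0.024	0.686	0.043	0.397	0.344
Ajuga	A. pygmaea	NE	150PE-3	0.721	0.025	0.633	0.044	0.389	0.332
Ajuga	A. shikotanensis	NE	100PE	0.740	0.451	0.502	0.012	0.318	0.194
Ajuga	A. shikotanensis	NE	150PE-1	0.734	0.414	0.512	0.023	0.320	0.208
Ajuga	A. shikotanensis	NE	150PE-2	0.748	0.456	0.497	0.018	0.317	0.197
Crepidiastrum	C. grandicollum	EIE	100PE	0.696	0.170	0.593	0.020	0.388	0.256
Crepidiastrum	C. grandicollum	EIE	90PE	0.707	0.200	0.589	0.024	0.385	0.226
Crepidiastrum	C. grandicollum	EIE	150PE-1	0.642	0.149	0.611	0.035	0.414	0.281
Crepidiastrum	C. grandicollum	EIE	150PE-2	0.659	0.153	0.610	0.035	0.427	0.282
Crepidiastrum	C. ameristophyllum	EIE	100PE	0.721	0.133	0.599	0.024	0.386	0.260
Crepidiastrum	C. linguifolium	EIE	90PE-1	0.679	0.128	0.577	0.026	0.377	0.231
Crepidiastrum	C. linguifolium	EIE	90PE-2	0.696	0.130	0.608	0.033	0.377	0.257
Crepidiastrum	C. lanceolatum	NE	100PE	0.730	0.344	0.486	0.015	0.275	0.184
Crepidiastrum	C. lanceolatum	NE	150PE-1	0.775	0.158	0.496	0.025	0.290	0.197
Crepidiastrum	C. lanceolatum	NE	150PE-2	0.771	0.260	0.488	0.021	0.269	0.188
Crepidiastrum	C. keiskeanum	NE	90PE	0.717	0.283	0.512	0.017	0.320	0.202
Calanthe	C. hoshii	EIE	150PE-1	0.709	0.119	0.591	0.023	0.361	0.264
Calanthe	C. hoshii	EIE	150PE-2	0.716	0.116	0.584	0.031	0.360	0.253
Calanthe	C. hoshii	EIE	150PE-3	0.702	0.150	0.567	0.025	0.349	0.248
Calanthe	C. triplicata	NE	150PE-1	0.736	0.261	0.505	0.015	0.261	0.214
Calanthe	C. triplicata	NE	150PE-2	0.758	0.262	0.508	0.025	0.260	0.206
Calanthe	C. triplicata	NE	150PE-3	0.760	0.244	0.505	0.028	0.267	0.214
Melastoma	M. tetramerum	EIE	150PE-1	0.695	0.101	0.585	0.018	0.381	0.261
Melastoma	M. tetramerum	EIE	150PE-2	0.702	0.100	0.588	0.017	0.369	0.248
Melastoma	M. tetramerum	EIE	150PE-3	0.704	0.099	0.614	0.022	0.378	0.255
Melastoma	M. candidum	NE	150PE-1	0.692	0.326	0.511	0.012	0.309	0.212
Melastoma	M. candidum	NE	150PE-2	0.721	0.329	0.474	0.013	0.286	0.207
Melastoma	M. candidum	NE	150PE-3	0.697	0.427	0.503	0.013	0.280	0.204
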