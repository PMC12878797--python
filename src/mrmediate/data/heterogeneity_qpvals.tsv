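id.exposure	id.outcome	method	Q_pval
GCST90199644	ieu-b-4961	Inverse variance weighted	0.585258918
GCST90199645	ieu-b-4961	Inverse variance weighted	0.881251407
GCST90199701	ieu-b-4961	Inverse variance weighted	0.782204259
GCST90199716	ieu-b-4961	Inverse variance weighted	0.651261894
GCST90199745	ieu-b-4961	Inverse variance weighted	0.718152447
GCST90199770	ieu-b-4961	Inverse variance weighted	0.229715049
GCST90199786	ieu-b-4961	Inverse variance weighted	0.16289662
GCST90199805	ieu-b-4961	Inverse variance weighted	0.917879159
GCST90199811	ieu-b-4961	Inverse variance weighted	0.516588722
GCST90199820	ieu-b-4961	Inverse variance weighted	0.847240802
GCST90199812	ieu-b-4961	Inverse variance weighted	0.566181418
GCST90199811	ieu-b-4961	Inverse variance weighted	0.806679286
GCST90199852	ieu-b-4961	Inverse variance weighted	0.796809792
GCST90199861	ieu-b-4961	Inverse variance weighted	0.626661466
GCST90199864	ieu-b-4961	Inverse variance weighted	0.772848272
GCST90199924	ieu-b-4961	Inverse variance weighted	0.927621954
GCST90199941	ieu-b-4961	Inverse variance weighted	0.454565227
GCST90199951	ieu-b-4961	Inverse variance weighted	0.792209511
GCST90200028	ieu-b-4961	Inverse variance weighted	0.418794107
GCST90200049	ieu-b-4961	Inverse variance weighted	0.898125426
GCST90200080	ieu-b-4961	Inverse variance weighted	0.811192919
GCST90200088	ieu-b-4961	Inverse variance weighted	0.487912459
GCST90200094	ieu-b-4961	Inverse variance weighted	0.961486458
GCST90200142	ieu-b-4961	Inverse variance weighted	0.744164021
GCST90200149	ieu-b-4961	Inverse variance weighted	0.444972276
GCST90200211	ieu-b-4961	Inverse variance weighted	0.828506621
GCST90200228	ieu-b-4961	Inverse variance weighted	0.718798151
GCST90200214	ieu-b-4961	Inverse variance weighted	0.817818058
GCST90200215	ieu-b-4961	Inverse variance weighted	0.526471074
GCST90200258	ieu-b-4961	Inverse variance weighted	0.115710847
GCST90200262	ieu-b-4961	Inverse variance weighted	0.414111204
GCST90200276	ieu-b-4961	Inverse variance weighted	0.615188011
GCST90200284	ieu-b-4961	Inverse variance weighted	0.588001912
GCST90200286	ieu-b-4961	Inverse variance weighted	0.755409611
GCST90200119	ieu-b-4961	Inverse variance weighted	0.541851279
GCST90200151	ieu-b-4961	Inverse variance weighted	0.758801019
GCST90200170	ieu-b-4961	Inverse variance weighted	0.888848618
GCST90200195	ieu-b-4961	Inverse variance weighted	0.751871008
GCST90200408	ieu-b-4961	Inverse variance weighted	0.972514192
GCST90200416	ieu-b-4961	Inverse variance weighted	0.254761266
GCST90200428	ieu-b-4961	Inverse variance weighted	0.410456514
GCST90200412	ieu-b-4961	Inverse variance weighted	0.295664627
GCST90200447	ieu-b-4961	Inverse variance weighted	0.701948876
GCST90200498	ieu-b-4961	Inverse variance weighted	0.604886519
GCST90200507	ieu-b-4961	Inverse variance weighted	0.617608407
GCST90200511	ieu-b-4961	Inverse variance weighted	0.549099111
GCST90200542	ieu-b-4961	Inverse variance weighted	0.89141885
GCST90200570	ieu-b-4961	Inverse variance weighted	0.968101699
GCST90200575	ieu-b-4961	Inverse variance weighted	0.815911728
GCST90200664	ieu-b-4961	Inverse variance weighted	0.967711911
GCST90200665	ieu-b-4961	Inverse variance weighted	0.615822728
GCST90200680	ieu-b-4961	Inverse variance weighted	0.792805051
GCST90200714	ieu-b-4961	Inverse variance weighted	0.607416807
GCST90200718	ieu-b-4961	Inverse variance weighted	0.478259685
GCST90200761	ieu-b-4961	Inverse variance weighted	0.669144415
GCST90200767	ieu-b-4961	Inverse variance weighted	0.259090571
GCST90200785	ieu-b-4961	Inverse variance weighted	0.565616288
GCST90200824	ieu-b-4961	Inverse variance weighted	0.418447852
GCST90200849	ieu-b-4961	Inverse variance weighted	0.9541885
GCST90200910	ieu-b-4961	Inverse variance weighted	0.111125107
GCST90200910	ieu-b-4961	Inverse variance weighted	0.450120412
GCST90200916	ieu-b-4961	Inverse variance weighted	0.598119099
GCST90200985	ieu-b-4961	Inverse variance weighted	0.0602455421
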