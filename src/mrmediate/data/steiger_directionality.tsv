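id.exposure	id.outcome	correct_causal_direction	steiger_pval
GCST90199644	ieu-b-4961	TRUE	2.46e-61
GCST90199645	ieu-b-4961	TRUE	1.29e-28
GCST90199701	ieu-b-4961	TRUE	1.15e-56
GCST90199716	ieu-b-4961	TRUE	6.27e-160
GCST90199745	ieu-b-4961	TRUE	1.89e-41
GCST90199770	ieu-b-4961	TRUE	2.17e-95
GCST90199786	ieu-b-4961	TRUE	1.26e-71
GCST90199805	ieu-b-4961	TRUE	1.72e-97
GCST90199811	ieu-b-4961	TRUE	1.49e-64
GCST90199820	ieu-b-4961	TRUE	1.21e-19
GCST90199812	ieu-b-4961	TRUE	6.71e-49
GCST90199811	ieu-b-4961	TRUE	1.66e-211
GCST90199852	ieu-b-4961	TRUE	1.16e-81
GCST90199861	ieu-b-4961	TRUE	4.89e-179
GCST90199864	ieu-b-4961	TRUE	1.01e-76
GCST90199924	ieu-b-4961	TRUE	1.56e-61
GCST90199941	ieu-b-4961	TRUE	1.05e-18
GCST90199951	ieu-b-4961	TRUE	9.07e-16
GCST90200028	ieu-b-4961	TRUE	7.07e-71
GCST90200049	ieu-b-4961	TRUE	1.76e-65
GCST90200080	ieu-b-4961	TRUE	9.99e-104
GCST90200088	ieu-b-4961	TRUE	1.68e-92
GCST90200094	ieu-b-4961	TRUE	5.06e-51
GCST90200142	ieu-b-4961	TRUE	1.50e-97
GCST90200149	ieu-b-4961	TRUE	1.01e-205
GCST90200211	ieu-b-4961	TRUE	1.64e-29
GCST90200228	ieu-b-4961	TRUE	5.25e-78
GCST90200214	ieu-b-4961	TRUE	8.48e-45
GCST90200215	ieu-b-4961	TRUE	2.06e-165
GCST90200258	ieu-b-4961	TRUE	2.41e-91
GCST90200262	ieu-b-4961	TRUE	1.12e-118
GCST90200276	ieu-b-4961	TRUE	4.82e-10
GCST90200284	ieu-b-4961	TRUE	5.77e-16
GCST90200286	ieu-b-4961	TRUE	1.05e-14
GCST90200119	ieu-b-4961	TRUE	6.82e-16
GCST90200151	ieu-b-4961	TRUE	2.05e-272
GCST90200170	ieu-b-4961	TRUE	1.69e-69
GCST90200195	ieu-b-4961	TRUE	2.90e-52
GCST90200408	ieu-b-4961	TRUE	4.41e-29
GCST90200416	ieu-b-4961	TRUE	1.51e-108
GCST90200428	ieu-b-4961	TRUE	2.21e-14
GCST90200412	ieu-b-4961	TRUE	9.10e-107
GCST90200447	ieu-b-4961	TRUE	5.48e-40
GCST90200498	ieu-b-4961	TRUE	5.14e-20
GCST90200507	ieu-b-4961	TRUE	2.48e-91
GCST90200511	ieu-b-4961	TRUE	6.60e-41
GCST90200542	ieu-b-4961	TRUE	1.17e-50
GCST90200570	ieu-b-4961	TRUE	4.77e-229
GCST90200575	ieu-b-4961	TRUE	1.96e-171
GCST90200664	ieu-b-4961	TRUE	1.19e-51
GCST90200665	ieu-b-4961	TRUE	2.02e-117
GCST90200680	ieu-b-4961	TRUE	4.69e-285
GCST90200714	ieu-b-4961	TRUE	4.07e-47
GCST90200718	ieu-b-4961	TRUE	1.47e-70
GCST90200761	ieu-b-4961	TRUE	2.92e-88
GCST90200767	ieu-b-4961	TRUE	8.69e-46
GCST90200785	ieu-b-4961	TRUE	4.65e-154
GCST90200824	ieu-b-4961	TRUE	9.40e-12
GCST90200849	ieu-b-4961	TRUE	1.16e-42
GCST90200910	ieu-b-4961	TRUE	1.12e-120
GCST90200910	ieu-b-4961	TRUE	2.17e-14
GCST90200916	ieu-b-4961	TRUE	8.72e-17
GCST90200985	ieu-b-4961	TRUE	6.11e-114
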