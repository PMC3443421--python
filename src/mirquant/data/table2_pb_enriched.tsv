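name	locations	pb_rpkm	cb_rpkm	fold	pb_rank	cb_rank
hsa-let-7b*	chr22:46509625-46509646	358.35938	26.206163	-13.67462226	91	280
hsa-mir-15b*	chr3:160122433-160122454	695.9995	72.2731	-9.630132096	73	215
hsa-mir-1290	chr1:19223572-19223590	337.0359	35.74031	-9.43013365	95	258
hsa-mir-15b	chr3:160122395-160122416	2379.7402	379.11118	-6.27715648	42	104
hsa-mir-574-3p	chr4:38869713-38869734	435.55652	86.03938	-5.062292639	85	201
hsa-mir-25	chr7:99691194-99691215	1534.8059	319.06284	-4.810356167	49	111
hsa-mir-148a	chr7:25989542-25989563	1073.8528	231.33844	-4.641912516	63	134
hsa-mir-30e*	chr1:41220085-41220106	3634.1675	920.4779	-3.948131183	34	76
hsa-mir-30a*	chr6:72113257-72113278	4051.6772	1061.4753	-3.817024475	29	74
hsa-mir-365	chr16:14403197-14403218,chr17:29902497-29902518	653.44617	171.86374	-3.802117713	75	149
hsa-mir-28-3p	chr3:188406622-188406643	1804.1597	485.26227	-3.717906401	44	96
hsa-mir-23b	chr9:97847547-97847567	8076.4937	2225.3198	-3.629363159	22	45
hsa-mir-146b-5p	chr10:104196277-104196298	1253.9794	349.96533	-3.583153223	58	108
hsa-mir-92b	chr1:155165028-155165049	318.21985	90.19796	-3.528016044	99	195
hsa-mir-197	chr1:110141562-110141583	528.68317	149.92363	-3.526349849	79	156
hsa-mir-140-3p	chr16:69967045-69967065	12527.033	3577.7405	-3.501381109	12	32
hsa-mir-598	chr8:10892731-10892752	489.91757	143.68575	-3.40964619	80	161
hsa-let-7b	chr22:46509571-46509592	8703.284	2554.5288	-3.407001714	20	40
hsa-mir-378	chr5:149112430-149112450	32406.646	10804.972	-2.999234612	7	9
hsa-mir-455-3p	chr9:116971767-116971787	548.25714	187.93459	-2.917276378	78	142
hsa-mir-193b	chr16:14397874-14397895	415.28253	143.25558	-2.898892525	87	162
hsa-mir-92a	chrX:133303574-133303595,chr13:92003615-92003636	3847.525	1331.7456	-2.889084071	33	64
hsa-mir-93	chr7:99691438-99691460	3588.8904	1322.95	-2.712793681	35	65
hsa-let-7c	chr21:17912158-17912179	15608.78	5758.0083	-2.710794981	11	22
hsa-mir-30b	chr8:135812813-135812834	1066.1298	400.58517	-2.661431026	64	100
hsa-mir-10a	chr17:46657266-46657288	17177.37	6494.583	-2.644876507	8	17
hsa-mir-10b	chr2:177015057-177015079	16707.91	6317.509	-2.644699042	10	19
hsa-let-7d	chr9:96941123-96941144	9057.177	3642.2817	-2.48667669	16	31
hsa-mir-151-3p	chr8:141742686-141742706	17066.672	7218.801	-2.3641976	9	16
hsa-mir-30c	chr1:41222972-41222994,chr6:72086706-72086728	4914.325	2188.866	-2.245146574	27	46
hsa-let-7e	chr19:52196046-52196067	8924.559	3985.3586	-2.239336505	17	29
hsa-mir-320a	chr8:22102488-22102509	757.8811	340.61673	-2.225026058	70	109
hsa-let-7a	chr11:122017276-122017297,chr9:96938244-96938265,chr22:46508632-46508653	65673.34	30296.24	-2.16770596	3	5
hsa-mir-99b	chr19:52195871-52195892	8875.32	4099.9907	-2.164717105	19	28
hsa-let-7f	chr9:96938635-96938656,chrX:53584207-53584228	37668.82	17587.143	-2.141838501	6	6
hsa-mir-23a	chr19:13947409-13947429	10271.966	4879.2725	-2.105224908	14	26
hsa-mir-125b	chr21:17962573-17962594,chr11:121970517-121970538	3983.9465	1976.1088	-2.016056252	30	51
hsa-mir-125a-5p	chr19:52196521-52196544	1764.7084	897.535	-1.966172238	46	79
hsa-mir-361-5p	chrX:85158686-85158707	399.24158	205.20401	-1.945583714	89	138
hsa-mir-16	chr3:160122542-160122563,chr13:50623163-50623184	3338.2983	1761.0107	-1.895671787	38	57
hsa-mir-1307	chr10:105154058-105154079	553.6359	294.46994	-1.880110072	77	118
hsa-mir-320b	chr1:224444751-224444772,chr1:117214409-117214430	661.5061	356.97238	-1.853101632	74	107
hsa-mir-217	chr2:56210155-56210177	10865.332	5983.509	-1.815879612	13	21
hsa-mir-769-5p	chr19:46522219-46522240	421.96628	236.17818	-1.786643796	86	133
hsa-mir-191	chr3:49058105-49058127	3378.5552	1927.2273	-1.753065246	36	52
hsa-mir-139-5p	chr11:72326147-72326168	301.21347	178.96194	-1.683114689	101	145
hsa-mir-26a	chr12:58218441-58218462,chr3:38010904-38010925	3344.9814	2055.193	-1.627575318	37	49
hsa-mir-103a	chr5:167987909-167987931,chr20:3898188-3898210	8117.7095	5296.3853	-1.532688624	21	23
hsa-mir-107	chr10:91352513-91352535	3862.0547	2533.423	-1.524441319	31	41
hsa-mir-151b	chr14:100575775-100575792	610.3607	405.608	-1.504804392	76	99
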