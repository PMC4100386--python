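dataset	chrom	band	start_pos	end_pos	size_kb	cnv_type
EAGLE	1	1p36.22	12120766	12129342	8.6	Deletion
EAGLE	5	5q35.2	175888783	175901659	12.9	Deletion
EAGLE	8	8q23.3	113681735	113741162	59.4	Amplification
EAGLE	8	8q24.3	144694717	144728743	34.0	Deletion
EAGLE	8	8q24.3	145079175	145118650	39.5	Deletion
EAGLE	9	9q32	114406899	114414974	8.1	Deletion
EAGLE	9	9q34.3	138620438	138641922	21.5	Deletion
EAGLE	10	10q22.3	80766077	80778488	12.4	Deletion
EAGLE	11	11q13.1	65012165	65051406	39.2	Deletion
EAGLE	13	13q21.1	56772821	56803216	30.4	Amplification
EAGLE	16	16p13.3	1951065	1994156	43.1	Deletion
EAGLE	17	17q21.1	35509120	35510616	1.5	Deletion
EAGLE	17	17q25.3	73635123	73655682	20.6	Deletion
EAGLE	17	17q25.3	77848326	78009203	160.9	Deletion
EAGLE	18	18p11.32	2580764	2629683	48.9	Deletion
EAGLE	18	18q22.1	64897188	64906488	9.3	Amplification
EAGLE	19	19p13.3	1046061	1126396	80.3	Deletion
EAGLE	19	19p13.3	1994271	2001823	7.6	Deletion
EAGLE	19	19p13.3	2050820	2079054	28.2	Deletion
EAGLE	20	20q13.33	61642713	61668792	26.1	Abnormal
EAGLE	21	21q22.3	45769452	45788806	19.4	Deletion
EAGLE	22	22q13.1	37667446	37704618	37.2	Deletion
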