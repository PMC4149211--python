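sample_id	gene	function_class	damaging_tally	chrom	start	ref	obs
32	GPS2	splice_site		chr17	7217225	C	T
41	KDM6A	frameshift		chrX	44969494	-	G
17	MLL3	nonsynonymous	4/4	chr7	151859899	G	A
16	MLL3	nonsynonymous	2/4	chr7	151860230	G	C
16	MLL3	nonsynonymous	1/4	chr7	151877127	G	T
21	MLL3	nonsynonymous	4/4	chr7	151879265	G	T
21	MLL3	stopgain		chr7	151900023	A	T
13	MLL3	stopgain		chr7	151874686	G	A
21	MLL3	nonsynonymous	3/4	chr7	151875073	G	A
30	MLL3	nonsynonymous	3/3	chr7	151927021	C	A
28	MLL3	nonsynonymous	1/4	chr7	151919690	C	T
33	MLL3	nonsynonymous	3/4	chr7	151970877	G	A
20	MLL3	nonsynonymous	2/4	chr7	151945568	C	T
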