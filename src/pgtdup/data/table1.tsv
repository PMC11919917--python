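RSID	POS	Distance	Male	Paternal hap 1	Paternal hap 2	Female	Proband	E1	E2	E3	E4	E5
rs1747899	144,939,820	-1366043	C/G	C	G	C/C	C/C	C/C	C/G	C/C	C/C	C/G
rs117176741	145,555,016	-750847	A/T	T	A	A/A	A/T	A/T	A/A	A/T	A/T	A/A
rs11804687	145,569,027	-736836	A/C	C	A	C/C	C/C	C/C	A/C	C/C	C/C	A/C
rs10910830	145,587,540	-718323	C/G	G	C	C/C	C/G	C/G	C/C	C/G	C/G	C/C
rs3754342	145,595,542	-710321	G/C	C	G	G/G	G/C	G/C	G/G	G/C	G/C	G/G
rs11591191	145,675,931	-629932	T/C	T	C	T/T	T/T	T/T	T/C	T/T	T/T	T/C
rs12750384	145,681,484	-624379	T/C	T	C	T/T	T/T	T/T	T/C	T/T	T/T	T/C
rs1023945	145,703,115	-602748	T/C	T	C	T/T	T/T	T/T	T/C	T/T	T/T	T/C
rs1970612	145,703,590	-602273	G/T	G	T	G/G	G/G	G/G	G/T	G/G	G/G	G/T
rs74696952	146,791,849		T/C			T/T	T/T	T/T	T/C	T/T	T/T	T/C
rs117246310	146,793,088		T/G			T/T	T/T	T/T	./	T/T	T/T	T/G
rs2353991	146,933,543		T/A			A/A	A/A	A/A	T/A	A/A	A/A	T/A
rs74609846	147,045,875		C/G			C/C	C/C	C/C	C/G	C/C	C/C	C/G
rs183547578	147,186,471		C/T			C/C	C/C	C/C	./	C/C	C/C	C/T
rs3009468	147,825,454		A/G			A/A	A/A	A/A	A/G	A/A	A/A	A/G
rs2999617	147,825,662		T/C			T/T	T/T	T/T	T/C	T/T	T/T	T/C
rs55886213	147,825,732		C/G			C/C	C/C	C/C	C/G	C/C	C/C	C/G
rs2999618	147,825,763		G/A			G/G	G/G	G/G	G/A	G/G	G/G	G/A
rs2999619	147,825,765		G/A			G/G	G/G	G/G	G/A	G/G	G/G	G/A
rs17581597	149,860,372	1,867,966	C/T	T	C	C/C	C/T	C/T	C/C	C/T	C/T	C/C
rs141696447	149,903,396	1,910,990	C/A	A	C	C/C	C/A	C/A	C/C	C/A	C/A	C/C
rs117037899	149,934,524	1,942,118	G/A	G	A	G/G	G/G	G/G	G/A	G/G	G/G	G/A
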