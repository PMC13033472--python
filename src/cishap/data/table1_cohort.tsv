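proband_id	sex	allele1	origin1	allele2	origin2	phase_method	group
3500	F	g.28017719_28020678delinsTTT		g.28017719_28020678delinsTTT		CCS	two_PLP
1222	M	c.2228C>T		c.1327G>A		ND	two_PLP
1211	F	c.1901T>A	Pat	143kb/184kbCxSV	Mat	Trios	two_PLP
1180	F	g.28017719_28020678delinsTTT		g.28017719_28020678delinsTTT		ND	two_PLP
1148	M	c.1503+5G>A	Pat	c.163del	Mat	Trios	two_PLP
1238	M	c.1327G>A	Pat	c.1116+5G>A	Mat	Trios	two_PLP
1002	M	c.1503+5G>A		c.1327G>A		ND	two_PLP
1093	F	c.2310T>G		c.1465A>G		ND	two_PLP
1218	F	c.1025A>G	Pat	143kb/184kbCxSV	Mat	Trios	two_PLP
1232	M	143kb/184kbCxSV	Pat	c.1327G>A	Mat	Trios	two_PLP
1252	F	c.79G>A; c.1320G>C	Pat	c.79G>A; c.1320G>C	Mat	CCS	two_PLP
1261	M	g.28017719_28020678delinsTTT		g.28017719_28020678delinsTTT		CCS	two_PLP
1122	F	c.1327G>A		c.1327G>A		CCS	two_PLP
1078	F	c.274del	Pat	c.1327G>A	Mat	Trios	two_PLP
2035	F	g.27837375_28079574dup		c.1327G>A	Mat	Mat	two_PLP
2066	F	c.2207C>T		c.2201T>G		CCS	two_PLP
2091	M	143kbinverteddupCxSV	Pat	c.1327G>A	Mat	Trios	two_PLP
2105	F	c.1290T>A	Pat	c.1327G>A	Mat	CCS	two_PLP
2112	M	c.1327G>A		g.28017719_28020678delinsTTT		ND	two_PLP
2163	F	g.28017719_28020678delinsTTT		g.28017719_28020678delinsTTT		CCS	two_PLP
2180	M	c.1327G>A		c.2228C>T		ND	two_PLP
2189	F	c.79G>A; c.1320G>C	Pat	c.2330G>A	Mat	Trios	two_PLP
2208	F	c.2228C>T		g.27965350_27973636delinsACACAACTTCATTGATAATGGCCTCTATTTA		ND	two_PLP
2280	M	c.1465A>G		c.1327G>A		ND	two_PLP
2282	M	c.1327G>A	Pat	c.2228C>T	Mat	Trios	two_PLP
2379	F	c.1103C>T		c.1103C>T		CCS	two_PLP
2415	F	c.1327G>A		c.2433-22889T>A		ND	two_PLP
2418	F	c.1465A>G		c.1465A>G		CCS	two_PLP
2422	F	c.493C>T		g.27878517_28001141del		ND	two_PLP
2425	M	c.2228C>T		c.1327G>A		ND	two_PLP
2435	M	c.1327G>A	Pat	c.79G>A; c.1320G>C	Mat	CCS	two_PLP
2451	M	c.1465A>G		c.1327G>A		ND	two_PLP
2456	F	c.1103C>T		g.28017719_28020678delinsTTT		ND	two_PLP
2457	M	c.1327G>A		143kb/184kbCxSV			two_PLP
2461	F	c.1465A>G	Pat	c.2037G>C	Mat	Trios	two_PLP
2465	M	c.1255C>T		g.(23975851_24027348)_(28442183_28445507)del		CCS	two_PLP
2552	M	c.1103C>T		c.1349C>T		ND	two_PLP
2557	F	c.1076G>A		c.1076G>A		CCS	two_PLP
2587	F	c.1327G>A		c.1327G>A		CCS	two_PLP
2593	M	c.1465A>G	Pat	c.1327G>A	Mat	Trios	two_PLP
2612	M	g.28017719_28020678delinsTTT	Pat	c.1327G>A	Mat	Trios	two_PLP
2622	F	c.1327G>A	Pat	g.28017719_28020678delinsTTT	Mat	ND	two_PLP
2637	F	c.1365-1G>C		c.163dup		Trios	two_PLP
2669	F	c.928C>T		c.928C>T		CCS	two_PLP
2682	M	c.79G>A; c.1320G>C		c.1327G>A		CCS	two_PLP
2766	M	c.619_636del	Pat	c.1327G>A	Mat	Trios	two_PLP
2781	M	c.1327G>A	Pat	143kb/184kbCxSV	Mat	Trios	two_PLP
2847	F	c.1327G>A	Pat	c.1465A>G	Mat	Trios	two_PLP
2854	M	c.1349C>T		g.28017719_28020678delinsTTT		ND	two_PLP
2875	M	c.2228C>T	Pat	c.2020C>G	Mat	Trios	two_PLP
2897	M	c.401G>A		c.401G>A		CCS	two_PLP
2938	M	g.27878517_28001141del		g.27878517_28001141del		CCS	two_PLP
2946	M	c.2228C>T	Pat	c.1327G>A	Mat	Trios	two_PLP
2960	F	c.1182+1G>A		g.27844884_28020885del		CCS	two_PLP
2976	M	c.1465A>G		c.1327G>A		ND	two_PLP
3005	F	c.1327G>A	Pat	c.2228C>T	Mat	Trios	two_PLP
3029	F	g.28017719_28020678delinsTTT		c.1503+5G>A		ND	two_PLP
3030	F	c.1503+5G>A		g.28017719_28020678delinsTTT		ND	two_PLP
3032	M	c.2140-2A>G		g.28017719_28020678delinsTTT		ND	two_PLP
3034	F	c.1327G>A		c.612G>A		ND	two_PLP
3059	F	g.27844884_28020885del		g.[27975445_27984368dup;27984368_27984369insTTAACA]		CCS	two_PLP
3111	F	143kb/184kbCxSV	Pat	c.1327G>A	Mat	Trios	two_PLP
3112	M	c.1045_1046del	Pat	c.1922C>T	Mat	Trios	two_PLP
3117	F	c.228-2A>G		g.28017719_28020678delinsTTT		ND	two_PLP
3139	F	c.2244+2T>G	Pat	c.574-1G>A	Mat	Trios	two_PLP
3146	F	g.28017719_28020678delinsTTT		g.27973488_28073270dup		CCS	two_PLP
3188	F	c.79G>A; c.1320G>C		c.1327G>A		CCS	two_PLP
3192	F	c.1327G>A	Pat	c.1465A>G	Mat	Trios	two_PLP
3207	M	c.1327G>A		g.28017719_28020678delinsTTT		ND	two_PLP
3262	M	c.79G>A; c.1320G>C		143kb/184kbCxSV		ND	two_PLP
3264	F	c.406C>T		c.1255C>T		ND	two_PLP
3273	F	c.1349C>T	Pat	c.1636G>A	Mat	Trios	two_PLP
3285	M	c.2228C>T		c.2228C>T		CCS	two_PLP
3289	M	g.27979571_27984604del		g.27979571_27984604del		CCS	two_PLP
3290	F	g.27979571_27984604del		g.28017719_28020678delinsTTT		ND	two_PLP
3291	F	g.28017719_28020678delinsTTT		g.27979571_27984604del		ND	two_PLP
3293	F	g.28017719_28020678delinsTTT		g.28017719_28020678delinsTTT		CCS	two_PLP
3294	F	g.28017719_28020678delinsTTT		c.2360C>T		ND	two_PLP
3295	M	g.28017719_28020678delinsTTT		g.28017719_28020678delinsTTT		CCS	two_PLP
3296	M	g.27979571_27984604del		g.28017719_28020678delinsTTT		ND	two_PLP
3501	M	c.2324G>A		c.1239+5G>C		ND	one_PLP_one_VUS
1220	F	c.1897G>A		c.1255C>T	Mat	Mat	one_PLP_one_VUS
1225	M	c.1465A>G	Pat	c.1336A>G	Mat	Trios	one_PLP_one_VUS
2055	M	c.1327G>A	Pat	c.632C>T	Mat	Trios	one_PLP_one_VUS
2244	F	c.1095_1103del		c.1430T>C	Mat	ND	one_PLP_one_VUS
2546	M	c.1465A>G		c.2180T>C		ND	one_PLP_one_VUS
2556	M	c.2228C>T		c.1239+5G>C		ND	one_PLP_one_VUS
2666	F	g.28017719_28020678delinsTTT		c.632C>T		ND	one_PLP_one_VUS
2726	M	c.1951+1G>A		c.874T>C	Mat	Trios	one_PLP_one_VUS
2784	M	g.28017719_28020678delinsTTT	Pat	c.1239+5G>C	Mat	Trios	one_PLP_one_VUS
2837	F	c.819_822delinsGGTC	Pat	c.2359G>A	Mat	Trios	one_PLP_one_VUS
2856	M	c.414C>A	Pat	c.1336A>G	Mat	Trios	one_PLP_one_VUS
2912	M	c.700G>A	Pat	c.1465A>G	Mat	Trios	one_PLP_one_VUS
2981	F	c.2370_2375delinsCGT		c.79G>A; c.1320G>C	Mat	Mat	one_PLP_one_VUS
3064	F	c.1555del	Pat	c.632C>T	Mat	Trios	one_PLP_one_VUS
3258	M	c.2201T>G		c.631C>G		ND	one_PLP_one_VUS
3288	F	g.27979571_27984604del		c.2170G>C		ND	one_PLP_one_VUS
3292	F	g.27979571_27984604del		c.2170G>C		ND	one_PLP_one_VUS
3502	M	c.1239+5G>C		c.1239+5G>C		CCS	two_VUS
1209	M	c.1211C>T		c.2245-3_-2del	Mat	ND	two_VUS
1064	M	c.819_822delinsGGTC	Pat	c.2195C>T	Mat	Trios	two_VUS
1275	F	c.1239+5G>C		c.1239+5G>C		CCS	two_VUS
2431	F	c.757G>A	Pat	c.727C>T	Mat	CCS	two_VUS
2720	F	c.819_822delinsGGTC	Pat	c.874T>C	Mat	CCS	two_VUS
2795	F	c.819_822delinsGGTC		c.819_822delinsGGTC		CCS	two_VUS
2820	F	c.874T>C		c.874T>C		CCS	two_VUS
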