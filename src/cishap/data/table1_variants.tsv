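id	hgvs_c	hgvs_g	hgvs_p	vclass	contig	start	end	ref_allele	alt_allele	population_maf	anchor	retention_factor	aliases
exon7_del		g.28017719_28020678delinsTTT		sv_deletion	chr15	28017719	28020678			0.0011	0		g.28017719_28020678delinsTTT
c.2228C>T	c.2228C>T		p.Pro743Leu	missense	chr15	27877200	27877200	C	T		0		
c.1327G>A	c.1327G>A		p.Val443Ile	missense	chr15	27967300	27967300	G	A		0		
c.1901T>A	c.1901T>A			nonsense	chr15	27909900	27909900	T	A		0		
cxsv_143kb_184kb_del				cxsv	chr15	27874777	28094256				0		143kb/184kbCxSV
c.1503+5G>A	c.1503+5G>A			splice_region	chr15	27949695	27949695	G	A		0		
c.163del	c.163del		p.Ala55Leufs*47	frameshift_indel	chr15	28083700	28083700				0		
c.1116+5G>A	c.1116+5G>A			splice_region	chr15	27988395	27988395	G	A		0		
c.2310T>G	c.2310T>G			nonsense	chr15	27869000	27869000	T	G		0		
c.1465A>G	c.1465A>G		p.Asn489Asp	missense	chr15	27953500	27953500	A	G		0		
c.1025A>G	c.1025A>G			missense	chr15	27997500	27997500	A	G		0		
c.79G>A	c.79G>A		p.Gly27Arg	missense	chr15	28092100	28092100	G	A	0.0011	0		
c.1320G>C	c.1320G>C		p.Leu440Phe	missense	chr15	27968000	27968000	G	C	0.0002	0		
c.274del	c.274del		p.Ser92fs*10	frameshift_indel	chr15	28072600	28072600				0		
g.27837375_28079574dup		g.27837375_28079574dup		sv_duplication	chr15	27837375	28079574				0		g.27837375_28079574dup
c.2207C>T	c.2207C>T			missense	chr15	27879300	27879300	C	T		0		
c.2201T>G	c.2201T>G			missense	chr15	27879900	27879900	T	G		0		
cxsv_143kb_invdup				cxsv	chr15	28091876	28094256				0		143kbinverteddupCxSV
c.1290T>A	c.1290T>A			missense	chr15	27971000	27971000	T	A		0		
c.2330G>A	c.2330G>A		p.Cys777Tyr	missense	chr15	27867000	27867000	G	A		0		
g.27965350_27973636delins31		g.27965350_27973636delinsACACAACTTCATTGATAATGGCCTCTATTTA		sv_deletion	chr15	27965350	27973636				0		g.27965350_27973636delinsACACAACTTCATTGATAATGGCCTCTATTTA
c.1103C>T	c.1103C>T		p.Ala368Val	missense	chr15	27989700	27989700	C	T		0		
c.2433-22889T>A	c.2433-22889T>A			deep_intronic	chr15	27879589	27879589	T	A		0		
c.493C>T	c.493C>T			nonsense	chr15	28050700	28050700	C	T		0		
g.27878517_28001141del		g.27878517_28001141del		sv_deletion	chr15	27878517	28001141				0		g.27878517_28001141del
c.2037G>C	c.2037G>C			missense	chr15	27896300	27896300	G	C		0		
c.1255C>T	c.1255C>T		p.Arg419Trp	missense	chr15	27974500	27974500	C	T		0		
g.23975851_28445507del		g.(23975851_24027348)_(28442183_28445507)del		sv_deletion	chr15	23975851	28445507				0		g.(23975851_24027348)_(28442183_28445507)del
c.1349C>T	c.1349C>T		p.Thr450Met	missense	chr15	27965100	27965100	C	T		0		
c.1076G>A	c.1076G>A			missense	chr15	27992400	27992400	G	A		0		
c.1365-1G>C	c.1365-1G>C			splice_region	chr15	27963501	27963501	G	C		0		
c.163dup	c.163dup			frameshift_indel	chr15	28083700	28083700				0		
c.928C>T	c.928C>T		p.Gln310Ter	nonsense	chr15	28007200	28007200	C	T		0		
c.619_636del	c.619_636del		p.Leu207_Leu212del	inframe_indel	chr15	28036400	28038100				0		
c.2020C>G	c.2020C>G		p.Leu674Val	missense	chr15	27898000	27898000	C	G		0		
c.401G>A	c.401G>A		p.Trp134Ter	nonsense	chr15	28059900	28059900	G	A		0		
c.1182+1G>A	c.1182+1G>A			splice_region	chr15	27981799	27981799	G	A		0		
g.27844884_28020885del		g.27844884_28020885del		sv_deletion	chr15	27844884	28020885				0		g.27844884_28020885del
c.2140-2A>G	c.2140-2A>G			splice_region	chr15	27886002	27886002	A	G		0		
c.612G>A	c.612G>A		p.Trp204Ter	nonsense	chr15	28038800	28038800	G	A		0		
g.27975445_27984368dupins		g.[27975445_27984368dup;27984368_27984369insTTAACA]		sv_duplication	chr15	27975445	27984369				0		g.[27975445_27984368dup;27984368_27984369insTTAACA]
c.1045_1046del	c.1045_1046del			frameshift_indel	chr15	27995400	27995500				0		
c.1922C>T	c.1922C>T		p.Ser641Leu	missense	chr15	27907800	27907800	C	T		0		
c.228-2A>G	c.228-2A>G			splice_region	chr15	28077202	28077202	A	G		0		
c.2244+2T>G	c.2244+2T>G			splice_region	chr15	27875598	27875598	T	G		0		
c.574-1G>A	c.574-1G>A			splice_region	chr15	28042601	28042601	G	A		0		
g.27973488_28073270dup		g.27973488_28073270dup		sv_duplication	chr15	27973488	28073270				0		g.27973488_28073270dup
c.406C>T	c.406C>T			nonsense	chr15	28059400	28059400	C	T		0		
c.1636G>A	c.1636G>A		p.Glu546Lys	missense	chr15	27936400	27936400	G	A		0		
exon14_del		g.27979571_27984604del		sv_deletion	chr15	27979571	27984604			4.6e-05	0		g.27979571_27984604del
c.2360C>T	c.2360C>T			missense	chr15	27864000	27864000	C	T		0		
c.2324G>A	c.2324G>A			missense	chr15	27867600	27867600	G	A		0		
c.1239+5G>C	c.1239+5G>C			splice_region	chr15	27976095	27976095	G	C		0		
c.1897G>A	c.1897G>A			missense	chr15	27910300	27910300	G	A		0		
c.1336A>G	c.1336A>G			missense	chr15	27966400	27966400	A	G		0		
c.632C>T	c.632C>T			missense	chr15	28036800	28036800	C	T		0		
c.1095_1103del	c.1095_1103del			inframe_indel	chr15	27989700	27990500				0		
c.1430T>C	c.1430T>C			missense	chr15	27957000	27957000	T	C		0		
c.2180T>C	c.2180T>C			missense	chr15	27882000	27882000	T	C		0		
c.1951+1G>A	c.1951+1G>A			splice_region	chr15	27904899	27904899	G	A		0		
c.874T>C	c.874T>C		p.Phe292Leu	missense	chr15	28012600	28012600	T	C		0		
c.819_822delinsGGTC	c.819_822delinsGGTC		p.Asn273_Trp274delinsLysVal	inframe_indel	chr15	28017800	28018100				0		
c.2359G>A	c.2359G>A		p.Ala787Thr	missense	chr15	27864100	27864100	G	A		0		
c.414C>A	c.414C>A		p.Tyr138Ter	nonsense	chr15	28058600	28058600	C	A		0		
c.700G>A	c.700G>A			missense	chr15	28030000	28030000	G	A		0		
c.2370_2375delinsCGT	c.2370_2375delinsCGT		p.Val792del	inframe_indel	chr15	27862500	27863000				0		
c.1555del	c.1555del			frameshift_indel	chr15	27944500	27944500				0		
c.631C>G	c.631C>G			missense	chr15	28036900	28036900	C	G		0		
c.2170G>C	c.2170G>C			missense	chr15	27883000	27883000	G	C		0		
c.1211C>T	c.1211C>T			missense	chr15	27978900	27978900	C	T		0		
c.2245-3_-2del	c.2245-3_-2del			splice_region	chr15	27875502	27875503				0		
c.2195C>T	c.2195C>T			missense	chr15	27880500	27880500	C	T		0		
c.757G>A	c.757G>A		p.Glu253Lys	missense	chr15	28024300	28024300	G	A		0		
c.727C>T	c.727C>T		p.Arg243Cys	missense	chr15	28027300	28027300	C	T		0		
rs1800401	c.913C>T		p.Arg305Trp	missense	chr15	28008700	28008700	C	T	0.05792	1		c.913C>T
rs1800404	c.1065G>A		p.Ala355=	synonymous	chr15	27993500	27993500	G	A	0.27	1	0.8	c.1065G>A
rs1800407	c.1256G>A		p.Arg419Gln	missense	chr15	27974400	27974400	G	A	0.068	1		c.1256G>A
rs1800414	c.1844A>G		p.His615Arg	missense	chr15	27915600	27915600	A	G	0.05	1		c.1844A>G
rs12913832				regulatory_snp	chr15	28120472	28120472	A	G	0.3	1	0.8	
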