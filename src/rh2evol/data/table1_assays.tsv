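ancestor	ancestor_node	ancestral_lambda	mutations	mutant_lambda	descendant	descendant_node	descendant_lambda	bold
AncAgnatha	1	503	E122Q	486	AncJawedFish	2	488	1
AncCyprini2	6	505	E122Q	489	zebrafish3		488	1
AncTeleost	3	491	Q122E	508	eel		506	1
AncCyprini1	5	489	Q122E	504	AncCyprini2	6	505	1
AncEuteleost1	7	488	Q122E	503	scabbardfishC		506	1
AncAgnatha	1	503	M207L	493	lamprey		492	1
AncTetrapod	11	488	M207L	481	coelacanth		478	1
AncEuteleost2	8	489	A292S	478	AncEuteleost3	9	474	1
AncEuteleost1	7	488	M207L	480	loosejaw		468	0
AncEuteleost4	10	524	E122Q	504	medakaC		492	0
AncSquamata	13	497	D83N	496	gecko		467	0
AncEuteleost2	8	489	Q122E	504	AncEuteleost4	10	524	0
AncEuteleost2	8	489	Y96T/Q122E/C213F	509	AncEuteleost4	10	524	0
AncEuteleost2	8	489	V60F/F74Y/Y96T/Q122E/T209V/C213F/I255V/L259M/A273G	510	AncEuteleost4	10	524	0
AncTetrapod	11	488	M44I	491	AncSauropsid	12	499	0
AncTetrapod	11	488	L40V/A42C/M44I/I50T/V87A/A166S/I205L/L214I/L309M	491	AncSauropsid	12	499	0
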