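node_label	node_number	lambda_max_nm	aa122	aa207	aa292	thick_branch	duplication	provenance
AncAgnatha	1	503	E	M	A	0	0	text
lamprey		492	E	L	A	1	0	text
AncJawedFish	2	488	Q	M	A	1	0	text
AncTeleost	3	491	Q	M	A	0	0	text
eel		506	E	M	A	1	0	text
AncClupeo	4	488	Q	M	A	0	0	text
AncCyprini1	5	489	Q	M	A	0	1	text
goldfish		511	Q	M	A	1	0	figure
Ancestor2		474	Q	M	A	1	1	text
zebrafish1		467	Q	M	A	0	0	figure
zebrafish2		476	Q	M	A	0	0	figure
AncCyprini2	6	505	E	M	A	1	1	text
zebrafish3		488	Q	M	A	1	0	text
zebrafish4		505	E	M	A	0	0	text
AncEuteleost1	7	488	Q	M	A	0	1	text
scabbardfishC		506	E	M	A	1	0	text
loosejaw		468	Q	M	A	1	0	text
AncEuteleost2	8	489	Q	M	A	0	1	text
AncEuteleost3	9	474	Q	M	S	1	0	text
medakaA		452	Q	M	S	1	0	text
tilapiaB		472	Q	M	S	0	0	text
AncEuteleost4	10	524	E	M	A	1	1	text
medakaC		492	Q	M	A	1	0	text
medakaB		516	E	M	A	0	0	text
tilapiaAa		528	E	M	A	0	0	text
tilapiaAb		518	E	M	A	0	0	text
bfinKillifish		530	E	M	A	0	0	text
AncTetrapod	11	488	Q	M	A	0	0	text
coelacanth		478	Q	L	A	1	0	text
AncSauropsid	12	499	Q	M	A	1	0	text
pigeon		503	Q	M	A	0	0	text
chicken		505	Q	M	A	0	0	text
zebrafinch		508	Q	M	A	0	0	text
AncSquamata	13	497	Q	M	A	0	0	text
gecko		467	Q	M	A	1	0	text
chameleon		495	Q	M	A	0	0	text
anole		495	Q	M	A	0	0	figure
italianLizard		495	Q	M	A	0	0	figure
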