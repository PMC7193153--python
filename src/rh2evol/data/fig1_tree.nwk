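(lamprey,((eel,((goldfish,(zebrafish1,zebrafish2)Ancestor2,(zebrafish3,zebrafish4)AncCyprini2)AncCyprini1,(scabbardfishC,loosejaw,((medakaA,tilapiaB)AncEuteleost3,(medakaC,medakaB,tilapiaAa,tilapiaAb,bfinKillifish)AncEuteleost4)AncEuteleost2)AncEuteleost1)AncClupeo)AncTeleost,(coelacanth,(pigeon,chicken,zebrafinch,(gecko,chameleon,anole,italianLizard)AncSquamata)AncSauropsid)AncTetrapod)AncJawedFish)AncAgnatha;
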