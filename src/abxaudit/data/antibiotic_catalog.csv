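atc_code,generic_name,atc4,spectrum,aware
J01AA02,doxycycline,J01AA,narrow,Access
J01AA07,tetracycline,J01AA,narrow,Access
J01CA01,ampicillin,J01CA,narrow,Access
J01CA04,amoxicillin,J01CA,narrow,Access
J01CE01,benzylpenicillin,J01CE,narrow,Access
J01CE02,phenoxymethylpenicillin,J01CE,narrow,Access
J01CF02,cloxacillin,J01CF,narrow,Access
J01CR02,amoxicillin/clavulanic acid,J01CR,broad,Access
J01CR05,piperacillin/tazobactam,J01CR,broad,Watch
J01DB01,cefalexin,J01DB,narrow,Access
J01DB04,cefazolin,J01DB,narrow,Access
J01DB05,cefadroxil,J01DB,narrow,Access
J01DB09,cefradine,J01DB,narrow,Access
J01DB90,cefathiamidine,J01DB,narrow,Unclassified
J01DC02,cefuroxime,J01DC,broad,Watch
J01DC04,cefaclor,J01DC,broad,Watch
J01DC10,cefprozil,J01DC,broad,Watch
J01DD01,cefotaxime,J01DD,broad,Watch
J01DD02,ceftazidime,J01DD,broad,Watch
J01DD04,ceftriaxone,J01DD,broad,Watch
J01DD08,cefixime,J01DD,broad,Watch
J01DD62,cefoperazone/sulbactam,J01DD,broad,Unclassified
J01DD63,cefoperazone/tazobactam,J01DD,broad,Unclassified
J01DE01,cefepime,J01DE,broad,Watch
J01EB02,sulfamethizole,J01EB,narrow,Access
J01EE01,sulfamethoxazole/trimethoprim,J01EE,narrow,Access
J01FA01,erythromycin,J01FA,broad,Watch
J01FA09,clarithromycin,J01FA,broad,Watch
J01FA10,azithromycin,J01FA,broad,Watch
J01FF01,clindamycin,J01FF,narrow,Access
J01GB03,gentamicin,J01GB,broad,Access
J01GB06,amikacin,J01GB,broad,Access
J01GB90,etimicin,J01GB,broad,Unclassified
J01MA02,ciprofloxacin,J01MA,broad,Watch
J01MA06,norfloxacin,J01MA,broad,Watch
J01MA12,levofloxacin,J01MA,broad,Watch
J01MA14,moxifloxacin,J01MA,broad,Watch
J01XX01,fosfomycin,J01XX,narrow,Reserve
J01XD01,metronidazole,J01XD,narrow,Access
J01XD02,tinidazole,J01XD,narrow,Access
J01XD03,ornidazole,J01XD,narrow,Access
P01AB01,metronidazole,P01AB,narrow,Access
P01AB02,tinidazole,P01AB,narrow,Access
P01AB03,ornidazole,P01AB,narrow,Access
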