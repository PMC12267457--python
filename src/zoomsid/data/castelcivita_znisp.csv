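# ZooMS counts (ZNISP) per reported category and cultural complex for the
# Grotta di Castelcivita assemblage, transcribed from the published site
# summary table.  "Fail" rows are sampled fragments without a successful
# ZooMS identification; column sums are 210 / 840 / 213 (total 1263).
category,Mousterian,Uluzzian,Protoaurignacian
Equus,3,338,107
Cervid,118,107,23
Capreolus capreolus,1,12,0
Cervid/Rupicapra,2,0,0
Bos/Bison,13,96,47
Capra sp.,21,14,4
Rupicapra,8,52,5
Rhinoceros,2,0,0
Unidentified Cervid,15,90,1
Unidentified Caprine,1,3,2
Artiodactyla,0,1,0
Sus sp.,2,13,0
Ursus sp.,3,2,0
Canid,1,1,0
Felis/Lynx/Ursus,2,0,0
Panthera/Crocuta,0,0,1
Carnivora,0,3,0
Fail,18,108,23
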