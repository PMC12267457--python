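# Morphological NISP per broad faunal category and cultural complex for the
# Castelcivita assemblage.  Best-effort transcription of the published
# summary table: several printed morphology cells are typographically
# ambiguous and the per-complex sums do not reconcile with the printed
# morphology column totals, so these values support the ZooMS-vs-morphology
# comparison only and are not fixture-grade counts.
category,Mousterian,Uluzzian,Protoaurignacian
Equid,33,73,10
Cervidae,190,108,74
Artiodactyla,0,0,0
Bos/Bison,14,17,6
Caprine,61,37,1
Rhinoceros,1,0,0
Sus sp.,7,8,7
Carnivore,17,34,0
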