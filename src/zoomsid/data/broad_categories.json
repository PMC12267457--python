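{
 "Equus": "Equid",
 "Cervid": "Cervidae",
 "Capreolus capreolus": "Cervidae",
 "Unidentified Cervid": "Cervidae",
 "Cervid/Rupicapra": "Artiodactyla",
 "Artiodactyla": "Artiodactyla",
 "Bos/Bison": "Bos/Bison",
 "Capra sp.": "Caprine",
 "Rupicapra": "Caprine",
 "Unidentified Caprine": "Caprine",
 "Rhinoceros": "Rhinoceros",
 "Sus sp.": "Sus sp.",
 "Ursus sp.": "Carnivore",
 "Canid": "Carnivore",
 "Felis/Lynx/Ursus": "Carnivore",
 "Panthera/Crocuta": "Carnivore",
 "Carnivora": "Carnivore"
}
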