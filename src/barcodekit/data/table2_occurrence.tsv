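source	family	species_label
historical	Rajidae	Amblyraja georgiana
historical	Rajidae	Bathyraja eatonii
historical	Rajidae	Bathyraja maccaini
historical	Paralepididae	Notolepis coatsorum
historical	Macrouridae	Macrourus caml
historical	Macrouridae	Macrourus whitsoni
historical	Macrouridae	Antimora rostrata
historical	Muraenolepididae	Muraenolepis marmorata
historical	Myctophidae	Electrona antarctica
historical	Myctophidae	Gymnoscopelus braueri
historical	Myctophidae	Gymnoscopelus nicholsi
historical	Bathylagidae	Bathylagus sp.
historical	Artedidraconidae	Artedidraco spp.
historical	Artedidraconidae	Pogonophryne permitini
historical	Bathydraconidae	Cygnodraco mawsoni
historical	Bathydraconidae	Gerlachea australis
historical	Bathydraconidae	Prionodraco evansii
historical	Bathydraconidae	Gymnodraco acuticeps
historical	Channichthyidae	Chaenodraco wilsoni
historical	Channichthyidae	Chionobathyscus dewitti
historical	Channichthyidae	Cryodraco spp.
historical	Nototheniidae	Lepidonotothen squamifrons
historical	Nototheniidae	Dissostichus mawsoni
historical	Nototheniidae	Pleuragramma antarctica
historical	Nototheniidae	Trematomus brachysoma
historical	Nototheniidae	Trematomus spp.
historical	Zoarcidae	Lycodichthys spp.
historical	Zoarcidae	Pachycara spp.
historical	Liparidae	Paraliparis leobergi
chinare	Paralepididae	Notolepis coatsorum
chinare	Macrouridae	Coryphaenoides lecointei
chinare	Macrouridae	Macrourus whitsoni
chinare	Muraenolepididae	Muraenolepis orangiensis
chinare	Muraenolepididae	Notomuraenobathys microcephalus
chinare	Myctophidae	Electrona antarctica
chinare	Myctophidae	Gymnoscopelus braueri
chinare	Myctophidae	Gymnoscopelus nicholsi
chinare	Myctophidae	Gymnoscopelus opisthopterus
chinare	Bathylagidae	Bathylagus antarcticus
chinare	Artedidraconidae	Artedidraco shackletoni
chinare	Artedidraconidae	Pogonophryne scotti
chinare	Bathydraconidae	Cygnodraco mawsoni
chinare	Bathydraconidae	Bathydraco antarcticus
chinare	Bathydraconidae	Prionodraco evansii
chinare	Bathydraconidae	Racovitzia glacialis
chinare	Channichthyidae	Chionodraco hamatus
chinare	Channichthyidae	Chionobathyscus dewitti
chinare	Nototheniidae	Trematomus pennellii
chinare	Nototheniidae	Trematomus scotti
chinare	Zoarcidae	Lycodichthys antarcticus
chinare	Zoarcidae	Lycenchelys aratrirostris
chinare	Liparidae	Careproctus longipectoralis
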