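species	min_inter	mean_inter	max_intra	mean_intra
Artedidraco shackletoni	0.0235	0.1779	0.0015	0.0010
Artedidraco skottsbergi	0.0235	0.1795	0.0046	0.0031
Bathydraco antarcticus	0.0358	0.1810	0.0093	0.0031
Bathylagus antarcticus	0.2350	0.2612	0.0310	0.0209
Careproctus longipectoralis	0.2386	0.2679	0.0171	0.0114
Chionobathyscus dewitti	0.0303	0.1905	0.0061	0.0041
Chionodraco hamatus	0.0303	0.1885	0.0031	0.0021
Coryphaenoides lecointei	0.2108	0.2531	0	0
Cygnodraco mawsoni	0.0694	0.1816	0.0015	0.0010
Electrona antarctica	0.1776	0.2297	0.0031	0.0012
Gymnoscopelus braueri	0.0262	0.2256	0.0015	0.0010
Gymnoscopelus nicholsi	0.0262	0.2344	0.0077	0.0062
Gymnoscopelus opisthopterus	0.0568	0.2273	0.0015	0.0010
Lycenchelys aratrirostris	0.0306	0.2299	0.0031	0.0021
Lycodichthys antarcticus	0.0306	0.2313	0.0218	0.0156
Macrourus whitsoni	0.2108	0.2622	0.0093	0.0013
Notomuraenobathys microcephalus	0.0825	0.2665	NA	NA
Muraenolepis orangiensis	0.0825	0.2596	NA	NA
Notolepis coatsorum	0.2128	0.2486	0.0398	0.0329
Pogonophryne scotti	0.0256	0.1824	0.0077	0.0062
Prionodraco evansii	0.0508	0.1796	0.0061	0.0022
Racovitzia glacialis	0.0358	0.1738	0.0031	0.0021
Trematomus pennellii	0.1001	0.2229	0.0015	0.0010
Trematomus scotti	0.1001	0.2201	0.0031	0.0015
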