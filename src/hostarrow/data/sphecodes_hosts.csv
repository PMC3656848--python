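species,spec_I,spec_II,spec_III,LS,LO,H,S,A,C,P,M,n_genera,sporadic_extra,eco_similar
S. albilabris,S,G,G,0,0,1,0,0,1,0,1,3,1,0
S. alternatus,S,S,S,0,0,1,0,0,0,0,0,1,0,1
S. autumnalis,S,S,S,0,0,0,0,0,0,1,0,1,0,1
S. clematidis,?,?,?,0,0,0,0,0,0,0,0,0,0,0
S. confertus,S,S,S,0,0,0,0,1,0,0,0,1,0,1
S. crassus,S,G,G,0,1,0,0,0,0,0,0,1,0,0
S. cristatus,S,S,G,0,1,0,1,0,0,0,0,2,1,1
S. croaticus,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. dusmeti,?,?,?,0,0,0,0,0,0,0,0,0,0,0
S. ephippius,G,G,G,1,1,1,1,1,0,0,0,3,0,0
S. ferruginatus,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. geoffrellus,S,G,G,0,1,0,0,0,0,0,0,1,0,0
S. gibbus,S,G,G,0,1,1,0,0,0,0,0,2,1,0
S. hyalinatus,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. longuloides,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. longulus,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. majalis,S,S,S,1,0,0,0,0,0,0,0,1,0,1
S. marginatus,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. miniatus,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. monilicornis,G,G,G,1,1,1,1,1,0,0,0,3,0,0
S. niger,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. nomioidis,?,?,?,0,0,0,0,0,0,0,0,0,0,0
S. olivieri,S,S,S,1,1,0,0,0,0,0,0,1,0,1
S. pellucidus,S,G,G,1,0,0,0,1,0,0,0,2,1,0
S. pinguiculus,S,S,S,0,0,0,1,0,0,0,0,1,0,1
S. pseudofasciatus,?,?,?,0,0,0,0,0,0,0,0,0,0,0
S. puncticeps,S,S,S,0,1,0,0,0,0,0,0,1,0,1
S. ranunculi,?,?,?,0,0,0,0,0,0,0,0,0,0,0
S. reticulatus,S,G,G,1,0,0,0,1,0,0,0,2,1,0
S. rubicundus,S,S,S,0,0,0,0,1,0,0,0,1,0,1
S. ruficrus,S,S,S,0,0,0,0,1,0,0,0,1,0,1
S. rufiventris,S,S,S,0,0,1,0,0,0,0,0,1,0,1
S. scabricollis,S,S,S,1,0,0,0,0,0,0,0,1,0,1
S. schenckii,S,S,S,1,0,0,0,0,0,0,0,1,0,1
S. sp. 17,?,?,?,0,0,0,0,0,0,0,0,0,0,0
S. spinulosus,S,S,S,1,0,0,0,0,0,0,0,1,0,1
S. zangheri,?,?,?,0,0,0,0,0,0,0,0,0,0,0
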