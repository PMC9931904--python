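symbol,gene_id,chromosome,expression,variant,cis,correlation,function,total_printed
Armcx1,78248,X,1,0,0,1,1,6
Fam83d,71878,2,0,1,1,1,1,9
Ift52,245866,2,1,0,0,1,1,6
Ada,11486,2,1,0,0,1,1,6
Matn4,17183,2,0,1,1,1,0,6
Ctsa,19025,2,1,0,0,1,1,6
Prex1,277360,2,1,1,1,1,1,10
Ankrd6,140577,4,0,0,1,1,1,7
Slc35a1,24060,4,1,1,1,1,0,7
C9orf72,73205,4,1,0,0,1,1,6
Col28a1,213945,6,0,1,1,1,0,6
Ica1,15893,6,1,1,1,1,0,7
Irx3,16373,8,1,1,1,1,1,10
Mmp2,17390,8,1,0,0,1,1,6
Gnao1,14681,8,1,0,0,1,1,6
Usb1,101985,8,1,1,1,1,0,7
Csnk2a2,13000,8,1,0,0,1,1,6
Gins3,78833,8,0,1,1,1,0,6
Cand1,71902,10,1,0,0,1,1,6
Lrig3,320398,10,0,1,0,1,1,7
Slc26a10,216441,10,1,1,1,1,0,7
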