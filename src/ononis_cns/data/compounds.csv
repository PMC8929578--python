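id,name,formula,skeleton_class,n_carbonyl_O,n_ether_O,n_hydroxyl,pka_list,logP,logD74,logPe
calycosin_d,Calycosin D,C16H12O5,isoflavone,1,2,2,6.48;9.21,2.48,2.21,-5.60
formononetin,Formononetin,C16H12O4,isoflavone,1,2,1,6.48,2.83,2.73,-5.00
sativanone,Sativanone,C17H16O5,isoflavanone,1,3,1,7.78,3.04,2.75,-4.76
onogenin,Onogenin,C17H14O6,isoflavanone,1,4,1,7.78,3.03,2.49,-4.73
medicarpin,Medicarpin,C16H14O4,pterocarpan,0,3,1,9.34,3.03,3.03,-4.45
maackiain,Maackiain,C16H12O5,pterocarpan,0,4,1,9.34,2.49,2.49,-4.48
pseudobaptigenin,Pseudobaptigenin,C16H10O5,isoflavone,1,3,1,,,,
calycosin,Calycosin,C16H12O5,isoflavone,1,2,2,,,,
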