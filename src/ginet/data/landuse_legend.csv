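code,name
1,construction
2,river
3,lake
4,other_water
5,forest
6,bareland
7,farmland
8,road
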