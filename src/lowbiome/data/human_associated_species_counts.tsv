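Escherichia	4
Pseudomonas	6
Burkholderia	3
Sphingomonas	1
Ralstonia	1
Methylobacterium	0
Bradyrhizobium	0
Cutibacterium	3
Delftia	1
Acidovorax	0
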