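# Illustrative frequent-NGS-contaminant genus list (Salter-style).
# Supply your own curated list for real analyses.
Ralstonia
Methylobacterium
Bradyrhizobium
Burkholderia
Sphingomonas
Phyllobacterium
Mesorhizobium
Herbaspirillum
Delftia
Acidovorax
Pelomonas
Cutibacterium
Escherichia
Pseudomonas
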