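strain	genus	proportion
Acinetobacter baumannii	Acinetobacter	0.05
Actinomyces odontolyticus	Actinomyces	0.05
Bacillus cereus	Bacillus	0.05
Bacteroides vulgatus	Bacteroides	0.05
Bifidobacterium adolescentis	Bifidobacterium	0.05
Clostridium beijerinckii	Clostridium	0.05
Cutibacterium acnes	Cutibacterium	0.05
Deinococcus radiodurans	Deinococcus	0.05
Enterococcus faecalis	Enterococcus	0.05
Escherichia coli	Escherichia	0.05
Helicobacter pylori	Helicobacter	0.05
Lactobacillus gasseri	Lactobacillus	0.05
Neisseria meningitidis	Neisseria	0.05
Porphyromonas gingivalis	Porphyromonas	0.05
Pseudomonas aeruginosa	Pseudomonas	0.05
Rhodobacter sphaeroides	Rhodobacter	0.05
Staphylococcus aureus	Staphylococcus	0.05
Staphylococcus epidermidis	Staphylococcus	0.05
Streptococcus agalactiae	Streptococcus	0.05
Streptococcus mutans	Streptococcus	0.05
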