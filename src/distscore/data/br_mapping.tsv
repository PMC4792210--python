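# Bacteriorhodopsin (H. salinarum) author-residue ranges for the MR reference
# bundle, in the PDB author numbering shared by wild-type bR entries (e.g. 1PY6).
# Anchor residues: Phe27 (1.50), Tyr57 (2.50), Arg82 (3.50), Gly122 (4.50),
# Leu152 (5.50), Trp182 (6.50), Lys216 (7.50).
structure_id	chain_id	helix_id	author_start	author_end	missing_labels
bR	A	A	11	32
bR	A	B	40	63
bR	A	C	78	99
bR	A	D	105	128
bR	A	E	132	159
bR	A	F	168	192
bR	A	G	202	226
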