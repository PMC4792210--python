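# Microbial-rhodopsin 7TM reference bundle: 7 helices, 170 residues.
# common_start/common_end are inclusive common-numbering labels; anchor_label is
# the most conserved position of each helix (the *.50 anchor), with its
# family-wide conservation percentage as optional metadata.
# family = microbial_rhodopsin
helix_id	common_start	common_end	anchor_label	anchor_conservation
A	1.34	1.55	1.50	64
B	2.33	2.56	2.50	95
C	3.46	3.67	3.50	98
D	4.33	4.56	4.50	95
E	5.30	5.57	5.50	70
F	6.36	6.60	6.50	98
G	7.36	7.60	7.50	100
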