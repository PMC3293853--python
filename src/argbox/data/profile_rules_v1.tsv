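# argbox transcription-profile rule table, version v1
# Columns h1..h5 hold the required ternary H_r code for contrasts c1..c5;
# "*" is a wildcard. Rules are matched top to bottom, first match wins.
# Type I: repressed by the regulator (up in the deletion mutant, c1 = +1),
#   subtypes by the arginine response (c2, c3) and interaction (c5).
# Type II: activated by the regulator (c1 = -1), mirror subtypes.
# Type III: arginine-stimulated with the regulator, downregulated without it.
# Type IV: arginine-stimulated regardless of the regulator.
# Type V: type-I-like arginine response without the strain effect.
type	subtype	h1	h2	h3	h4	h5
I	I.5	1	-1	1	*	1
I	I.4	1	-1	0	*	1
I	I.3	1	0	1	*	1
I	I.2	1	-1	-1	*	0
I	I.1	1	0	0	*	0
II	II.5	-1	1	-1	*	-1
II	II.4	-1	1	0	*	-1
II	II.3	-1	0	-1	*	-1
II	II.2	-1	1	1	*	0
II	II.1	-1	0	0	*	0
III	III	0	1	-1	*	-1
IV	IV	0	1	1	*	*
V	V	0	-1	*	*	*
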