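# Nucleobase-edge assignment rules for water-ribonucleotide contacts.
# One rule per row; residues column lists the ribonucleotides the rule
# applies to (comma separated, no "r" prefix).  Edit and pass to
# load_edge_tables() to override the built-in tables.
#
# kind=pair       two interacting atoms -> edge
# kind=single     one interacting atom, unambiguous -> edge
# kind=ambiguous  one interacting atom shared by two edges; the water-oxygen
#                 distance to adjacent1 vs adjacent2 decides (strictly closer
#                 to adjacent1 -> edge1, else edge2)
#
# kind	residues	atoms	edge	adjacent1	edge1	adjacent2	edge2
pair	A	N1,N6	WC	-	-	-	-
pair	G	N1,N2	WC	-	-	-	-
pair	G	N1,O6	WC	-	-	-	-
pair	C	N3,N4	WC	-	-	-	-
pair	C,U	N3,O2	WC	-	-	-	-
pair	U	N3,O4	WC	-	-	-	-
pair	A	N6,N7	HG	-	-	-	-
pair	G	N7,O6	HG	-	-	-	-
pair	A,G	N3,N9	SG	-	-	-	-
pair	A,G	N3,O2'	SG	-	-	-	-
pair	C,U	N1,O2	SG	-	-	-	-
pair	G	N2,N3	SG	-	-	-	-
pair	C,U	O2,O2'	SG	-	-	-	-
single	A,G	N1	WC	-	-	-	-
single	C	N4	WC	-	-	-	-
single	U	O4	WC	-	-	-	-
single	C,U	N3	WC	-	-	-	-
single	A,G	N7	HG	-	-	-	-
single	A,G	N3	SG	-	-	-	-
single	A,G	N9	SG	-	-	-	-
single	C,U	N1	SG	-	-	-	-
single	A,G,C,U	O2'	SG	-	-	-	-
ambiguous	A	N6	-	N1	WC	C5	HG
ambiguous	G	O6	-	N1	WC	C5	HG
ambiguous	G	N2	-	N1	WC	N3	SG
ambiguous	C,U	O2	-	N3	WC	N1	SG
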