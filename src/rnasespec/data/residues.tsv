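# RNA residue table. One row per residue code usable in sequences.
# code          short token; bracketed in sequence text when longer than one letter
# parent_base   unmodified base used for dinucleotide (NpN) classification
# formula       elemental formula of the internal chain residue
#               (nucleoside 3'(2')-monophosphate minus one water)
# base_formula  elemental formula of the neutral nucleobase (as released in a-B loss)
code	parent_base	formula	base_formula
A	A	C10H12N5O6P	C5H5N5
C	C	C9H12N3O7P	C4H5N3O
G	G	C10H12N5O7P	C5H5N5O
U	U	C9H11N2O8P	C4H4N2O2
m5C	C	C10H14N3O7P	C5H7N3O
m7G	G	C11H14N5O7P	C6H7N5O
m1A	A	C11H14N5O6P	C6H7N5
m22G	G	C12H16N5O7P	C7H9N5O
m2G	G	C11H14N5O7P	C6H7N5O
D	U	C9H13N2O8P	C4H6N2O2
Y	U	C9H11N2O8P	C4H4N2O2
m5U	U	C10H13N2O8P	C5H6N2O2
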