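# Four-class chemical partition of amino-acid residues used for
# pore-lining classification. Residues not listed are classed
# hydrophobic. Columns: residue name, class.
ASP acidic
GLU acidic
LYS basic
ARG basic
HIS basic
SER polar
THR polar
ASN polar
GLN polar
TYR polar
CYS polar
TRP polar
GLY polar
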