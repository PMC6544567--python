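# van der Waals radii by element (Å), heavy-atom model (hydrogens not used).
# columns: element <TAB> radius
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
Se	1.90
H	1.20
F	1.47
Cl	1.75
Br	1.85
I	1.98
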