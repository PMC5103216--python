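# feature-patterns	v1
# Pharmacophore feature substructure table.  The feature atom is the first
# atom of each SMARTS match.  Conventions: amide/anilide N is not an
# acceptor; amide N-H is a donor; ether (incl. methoxy/dioxole) O is an
# acceptor; Cl/Br/I on aromatic carbon is dual-typed halogen+hydrophobic.
# name	kind	smarts
carbonyl_oxygen	acceptor	[OX1]=[#6]
ether_hydroxyl_oxygen	acceptor	[OX2;+0]
pyridine_type_n	acceptor	[nX2;H0;+0]
imine_n	acceptor	[NX2;+0;!$([N]=O)]
nitrile_n	acceptor	[NX1;+0]
amine_n	acceptor	[NX3;+0;!$([NX3][C,S,P]=[O,S,N]);!$([NX3]a)]
n_h_donor	donor	[#7;H1,H2,H3;+0,+1]
o_h_donor	donor	[OX2H]
aryl_halide	halogen	[Cl,Br,I;$([*]-c)]
halide_on_carbon	hydrophobic	[F,Cl,Br,I;$([*]-[#6])]
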