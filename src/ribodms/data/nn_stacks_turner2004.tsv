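# RNA nearest-neighbor helix stacking free energies, 37 C, kcal/mol.
# Turner 2004 set (Watson-Crick values from Xia et al. 1998, Biochemistry
# 37:14719; GU wobble values from Mathews et al. 1999, JMB 288:911 /
# Turner & Mathews 2010 NNDB). Key is 5'x1x2 3' over 3'y1y2 5' written
# x1x2/y1y2; the table is symmetric under 180-degree rotation of the motif.
# The two tandem-GU motifs that the 2004 set treats as a special case
# (GG/UU and UU/GG) carry the Mathews-1999 stack value of -0.5.
stack	dg37
AA/UU	-0.9
AC/UG	-2.2
AG/UC	-2.1
AG/UU	-0.6
AU/UA	-1.1
AU/UG	-1.4
CA/GU	-2.1
CC/GG	-3.3
CG/GC	-2.4
CG/GU	-1.4
CU/GA	-2.1
CU/GG	-2.1
GA/CU	-2.4
GA/UU	-1.3
GC/CG	-3.4
GC/UG	-2.5
GG/CC	-3.3
GG/CU	-1.5
GG/UC	-2.1
GG/UU	-0.5
GU/CA	-2.2
GU/CG	-2.5
GU/UA	-1.4
GU/UG	1.3
UA/AU	-1.3
UA/GU	-1.0
UC/AG	-2.4
UC/GG	-1.5
UG/AC	-2.1
UG/AU	-1.0
UG/GC	-1.4
UG/GU	0.3
UU/AA	-0.9
UU/AG	-1.3
UU/GA	-0.6
UU/GG	-0.5
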