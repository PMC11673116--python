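# 1-(1H-pyrrol-3-yl)ethanol natural internal coordinates (45 = 3N-6).
# Monomer tags: P = pyrrole, E = ethanol, PE = intermonomer linkage.
# Ring atoms: C1-N2-C3-C4-C5 (five-membered aromatic); C5-C6 links the
# ethanol fragment C6(H15)(C7 H13 H14 H16)(O8 H17).
# Five-ring symmetry coefficients (ideal pentagon values):
#   A = cos(4π/5) = -0.809016994374947   B = cos(2π/5) = 0.309016994374947
#   C = sin(4π/5) =  0.587785252292473   D = sin(2π/5) = 0.951056516295154

[coordinate]
name = ring breathing (P)
bond 5 4  1
bond 1 5  1
bond 4 3  1
bond 2 1  1
bond 2 3  1

[coordinate]
name = ring stretching def. 1 (P)
bond 5 4  1
bond 1 5  0.309016994374947
bond 4 3  0.309016994374947
bond 2 1  -0.809016994374947
bond 2 3  -0.809016994374947

[coordinate]
name = ring stretching def. 2 (P)
bond 1 5  0.951056516295154
bond 4 3  -0.951056516295154
bond 2 1  0.587785252292473
bond 2 3  -0.587785252292473

[coordinate]
name = ring stretching def. 3 (P)
bond 5 4  1
bond 1 5  -0.809016994374947
bond 4 3  -0.809016994374947
bond 2 1  0.309016994374947
bond 2 3  0.309016994374947

[coordinate]
name = ring stretching def. 4 (P)
bond 1 5  0.587785252292473
bond 4 3  -0.587785252292473
bond 2 1  -0.951056516295154
bond 2 3  0.951056516295154

[coordinate]
name = C5-C6 stretch (PE)
bond 5 6  1

[coordinate]
name = C6-C7 stretch (E)
bond 6 7  1

[coordinate]
name = C6-O8 stretch (E)
bond 6 8  1

[coordinate]
name = C1-H9 stretch (P)
bond 1 9  1

[coordinate]
name = N2-H10 stretch (P)
bond 2 10  1

[coordinate]
name = C3-H11 stretch (P)
bond 3 11  1

[coordinate]
name = C4-H12 stretch (P)
bond 4 12  1

[coordinate]
name = C6-H15 stretch (E)
bond 6 15  1

[coordinate]
name = O8-H17 stretch (E)
bond 8 17  1

[coordinate]
name = CH3 sym. stretch (E)
bond 7 13  1
bond 7 14  1
bond 7 16  1

[coordinate]
name = CH3 stretch def. (E)
bond 7 13  2
bond 7 14  -1
bond 7 16  -1

[coordinate]
name = CH3 antisym. stretch (E)
bond 7 14  1
bond 7 16  -1

[coordinate]
name = ring bending (P)
angle 1 2 3  1
angle 2 1 5  -0.809016994374947
angle 2 3 4  -0.809016994374947
angle 1 5 4  0.309016994374947
angle 3 4 5  0.309016994374947

[coordinate]
name = ring shearing (P)
angle 2 1 5  -1.118033988749895
angle 2 3 4  1.118033988749895
angle 1 5 4  1.809016994374947
angle 3 4 5  -1.809016994374947

[coordinate]
name = C6-C5 P rock (PE)
angle 6 5 4  1
angle 6 5 1  -1

[coordinate]
name = C7-C6-O bend (E)
angle 8 6 7  1

[coordinate]
name = C5-C6 E wag (PE)
angle 5 6 7  1
angle 5 6 8  1

[coordinate]
name = C5-C6 E rock (PE)
angle 5 6 7  1
angle 5 6 8  -1

[coordinate]
name = C1-H9 rock (P)
angle 9 1 2  1
angle 9 1 5  -1

[coordinate]
name = N2-H10 rock (P)
angle 10 2 3  1
angle 10 2 1  -1

[coordinate]
name = C3-H11 rock (P)
angle 11 3 4  1
angle 11 3 2  -1

[coordinate]
name = C4-H12 rock (P)
angle 12 4 5  1
angle 12 4 3  -1

[coordinate]
name = C-O-H bend (E)
angle 17 8 6  1

[coordinate]
name = H15-C6-C5 rock (E)
angle 15 6 7  1
angle 15 6 8  1

[coordinate]
name = H15-C6-C5 wag (E)
angle 15 6 7  1
angle 15 6 8  -1

[coordinate]
name = CH3 umbrella (E)
angle 13 7 6  1
angle 14 7 6  1
angle 16 7 6  1
angle 14 7 16  -1
angle 13 7 14  -1
angle 13 7 16  -1

[coordinate]
name = CH3 rock (E)
angle 13 7 6  2
angle 14 7 6  -1
angle 16 7 6  -1

[coordinate]
name = CH3 wag (E)
angle 14 7 6  1
angle 16 7 6  -1

[coordinate]
name = CH3 scissor (E)
angle 14 7 16  2
angle 13 7 14  -1
angle 13 7 16  -1

[coordinate]
name = CH3 def. (E)
angle 13 7 14  1
angle 13 7 16  -1

[coordinate]
name = ring twisting (P)
torsion 1 5 4 3  1
torsion 4 3 2 1  0.309016994374947
torsion 3 2 1 5  0.309016994374947
torsion 5 4 3 2  -0.809016994374947
torsion 2 1 5 4  -0.809016994374947

[coordinate]
name = ring puckering (P)
torsion 4 3 2 1  1.809016994374947
torsion 3 2 1 5  -1.809016994374947
torsion 5 4 3 2  -1.118033988749895
torsion 2 1 5 4  1.118033988749895

[coordinate]
name = CH3 torsion (E)
torsion 13 7 6 8  1
torsion 14 7 6 8  1
torsion 16 7 6 8  1

[coordinate]
name = O-H torsion (E)
torsion 17 8 6 7  1

[coordinate]
name = P-E torsion (PE)
torsion 1 5 6 7  1
torsion 1 5 6 8  1
torsion 4 5 6 7  1
torsion 4 5 6 8  1

[coordinate]
name = C6-C5 P wag (PE)
oop 6 5 1 4  1

[coordinate]
name = C1-H9 wag (P)
oop 9 1 2 5  1

[coordinate]
name = N2-H10 wag (P)
oop 10 2 3 1  1

[coordinate]
name = C3-H11 wag (P)
oop 11 3 4 2  1

[coordinate]
name = C4-H12 wag (P)
oop 12 4 5 3  1
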