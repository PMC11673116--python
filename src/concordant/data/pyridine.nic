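# Pyridine natural internal coordinates (27 = 3N-6), C2v labels.
# Ring atoms 1-5 are carbon, atom 6 is nitrogen; H7-H11 sit on C1-C5.
# Coefficients are the unnormalized chemically-intuitive combinations;
# rows are normalized to unit Euclidean norm on load.

[coordinate]
name = ring breathing
irrep = a1
bond 5 3  1
bond 3 1  1
bond 1 2  1
bond 2 4  1
bond 4 6  1
bond 6 5  1

[coordinate]
name = ring stretching def. 1
irrep = b2
bond 5 3  1
bond 3 1  -1
bond 1 2  1
bond 2 4  -1
bond 4 6  1
bond 6 5  -1

[coordinate]
name = ring stretching def. 2
irrep = a1
bond 5 3  2
bond 3 1  -1
bond 1 2  -1
bond 2 4  2
bond 4 6  -1
bond 6 5  -1

[coordinate]
name = ring stretching def. 3
irrep = b2
bond 5 3  2
bond 3 1  1
bond 1 2  -1
bond 2 4  -2
bond 4 6  -1
bond 6 5  1

[coordinate]
name = ring stretching def. 4
irrep = a1
bond 3 1  1
bond 1 2  1
bond 4 6  -1
bond 6 5  -1

[coordinate]
name = ring stretching def. 5
irrep = b2
bond 3 1  1
bond 1 2  -1
bond 4 6  1
bond 6 5  -1

[coordinate]
name = sym. CH stretch (C5,C4)
irrep = a1
bond 5 11  1
bond 4 10  1

[coordinate]
name = antisym. CH stretch (C5,C4)
irrep = b2
bond 5 11  1
bond 4 10  -1

[coordinate]
name = sym. CH stretch (C3,C2)
irrep = a1
bond 3 9  1
bond 2 8  1

[coordinate]
name = antisym. CH stretch (C3,C2)
irrep = b2
bond 3 9  1
bond 2 8  -1

[coordinate]
name = CH stretch (C1)
irrep = a1
bond 1 7  1

[coordinate]
name = ring stellation
irrep = a1
angle 4 6 5  1
angle 6 5 3  -1
angle 5 3 1  1
angle 3 1 2  -1
angle 1 2 4  1
angle 2 4 6  -1

[coordinate]
name = ring rectangulation
irrep = a1
angle 4 6 5  2
angle 6 5 3  -1
angle 5 3 1  -1
angle 3 1 2  2
angle 1 2 4  -1
angle 2 4 6  -1

[coordinate]
name = ring shearing
irrep = b2
angle 6 5 3  1
angle 5 3 1  -1
angle 1 2 4  1
angle 2 4 6  -1

[coordinate]
name = sym. i.p. CH rock (C5,C4)
irrep = a1
angle 11 5 6  1
angle 11 5 3  -1
angle 10 4 6  1
angle 10 4 2  -1

[coordinate]
name = antisym. i.p. CH rock (C5,C4)
irrep = b2
angle 11 5 6  1
angle 11 5 3  -1
angle 10 4 6  -1
angle 10 4 2  1

[coordinate]
name = sym. i.p. CH rock (C3,C2)
irrep = a1
angle 9 3 5  1
angle 9 3 1  -1
angle 8 2 4  1
angle 8 2 1  -1

[coordinate]
name = antisym. i.p. CH rock (C3,C2)
irrep = b2
angle 9 3 5  1
angle 9 3 1  -1
angle 8 2 4  -1
angle 8 2 1  1

[coordinate]
name = i.p. CH rock (C1)
irrep = b2
angle 7 1 2  1
angle 7 1 3  -1

[coordinate]
name = chair ring pucker
irrep = b1
torsion 6 5 3 1  1
torsion 3 1 2 4  1
torsion 5 3 1 2  -1
torsion 1 2 4 6  -1
torsion 2 4 6 5  1
torsion 4 6 5 3  -1

[coordinate]
name = boat ring pucker
irrep = b1
torsion 3 1 2 4  1
torsion 5 3 1 2  -1
torsion 2 4 6 5  -1
torsion 4 6 5 3  1

[coordinate]
name = ring twist
irrep = a2
torsion 6 5 3 1  2
torsion 5 3 1 2  -1
torsion 3 1 2 4  -1
torsion 1 2 4 6  2
torsion 2 4 6 5  -1
torsion 4 6 5 3  -1

[coordinate]
name = sym. o.o.p. CH wag (C5,C4)
irrep = b1
oop 11 5 3 6  1
oop 10 4 6 2  1

[coordinate]
name = antisym. o.o.p. CH wag (C5,C4)
irrep = a2
oop 11 5 3 6  1
oop 10 4 6 2  -1

[coordinate]
name = sym. o.o.p. CH wag (C3,C2)
irrep = b1
oop 9 3 1 5  1
oop 8 2 4 1  1

[coordinate]
name = antisym. o.o.p. CH wag (C3,C2)
irrep = a2
oop 9 3 1 5  1
oop 8 2 4 1  -1

[coordinate]
name = o.o.p. CH wag (C1)
irrep = b1
oop 7 1 2 3  1
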