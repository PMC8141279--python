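MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF AP1
letter-probability matrix: alength= 4 w= 7 nsites= 20 E= 0
0.020000 0.020000 0.020000 0.940000
0.020000 0.020000 0.940000 0.020000
0.940000 0.020000 0.020000 0.020000
0.020000 0.940000 0.020000 0.020000
0.020000 0.020000 0.020000 0.940000
0.020000 0.940000 0.020000 0.020000
0.940000 0.020000 0.020000 0.020000

MOTIF TBET
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
0.940000 0.020000 0.020000 0.020000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.020000 0.940000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.020000 0.940000
0.020000 0.020000 0.940000 0.020000
0.940000 0.020000 0.020000 0.020000

MOTIF EGR2
letter-probability matrix: alength= 4 w= 9 nsites= 20 E= 0
0.020000 0.020000 0.940000 0.020000
0.020000 0.940000 0.020000 0.020000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.020000 0.940000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.940000 0.020000
0.020000 0.940000 0.020000 0.020000
0.020000 0.020000 0.940000 0.020000

MOTIF MspI
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
0.020000 0.940000 0.020000 0.020000
0.020000 0.940000 0.020000 0.020000
0.020000 0.020000 0.940000 0.020000
0.020000 0.020000 0.940000 0.020000

MOTIF TaqI
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
0.020000 0.020000 0.020000 0.940000
0.020000 0.940000 0.020000 0.020000
0.020000 0.020000 0.940000 0.020000
0.940000 0.020000 0.020000 0.020000

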