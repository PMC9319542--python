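# Davidson (1990) modified power-law representation of the Pasquill-Gifford (Briggs)
# dispersion curves, sigma = a * x**(b + c*ln(x)) with x in KILOMETRES, sigma in metres.
# Transcribed from Davidson, J. Air Waste Manage. Assoc. 40 (1990) 1146-1147, Table I.
class,coefficient,value,source
a,ay,209.6,Davidson (1990) JAWMA 40:1146 Table I
a,by,0.8804,Davidson (1990) JAWMA 40:1146 Table I
a,cy,-0.006902,Davidson (1990) JAWMA 40:1146 Table I
a,az,417.9,Davidson (1990) JAWMA 40:1146 Table I
a,bz,2.058,Davidson (1990) JAWMA 40:1146 Table I
a,cz,0.2499,Davidson (1990) JAWMA 40:1146 Table I
b,ay,154.7,Davidson (1990) JAWMA 40:1146 Table I
b,by,0.8932,Davidson (1990) JAWMA 40:1146 Table I
b,cy,-0.006271,Davidson (1990) JAWMA 40:1146 Table I
b,az,109.8,Davidson (1990) JAWMA 40:1146 Table I
b,bz,1.064,Davidson (1990) JAWMA 40:1146 Table I
b,cz,0.01163,Davidson (1990) JAWMA 40:1146 Table I
c,ay,103.3,Davidson (1990) JAWMA 40:1146 Table I
c,by,0.9112,Davidson (1990) JAWMA 40:1146 Table I
c,cy,-0.004845,Davidson (1990) JAWMA 40:1146 Table I
c,az,61.14,Davidson (1990) JAWMA 40:1146 Table I
c,bz,0.9147,Davidson (1990) JAWMA 40:1146 Table I
c,cz,0.0,Davidson (1990) JAWMA 40:1146 Table I
d,ay,68.28,Davidson (1990) JAWMA 40:1146 Table I
d,by,0.9112,Davidson (1990) JAWMA 40:1146 Table I
d,cy,-0.004845,Davidson (1990) JAWMA 40:1146 Table I
d,az,30.38,Davidson (1990) JAWMA 40:1146 Table I
d,bz,0.7309,Davidson (1990) JAWMA 40:1146 Table I
d,cz,-0.032,Davidson (1990) JAWMA 40:1146 Table I
e,ay,51.05,Davidson (1990) JAWMA 40:1146 Table I
e,by,0.9112,Davidson (1990) JAWMA 40:1146 Table I
e,cy,-0.004845,Davidson (1990) JAWMA 40:1146 Table I
e,az,21.14,Davidson (1990) JAWMA 40:1146 Table I
e,bz,0.6802,Davidson (1990) JAWMA 40:1146 Table I
e,cz,-0.04522,Davidson (1990) JAWMA 40:1146 Table I
f,ay,33.96,Davidson (1990) JAWMA 40:1146 Table I
f,by,0.9112,Davidson (1990) JAWMA 40:1146 Table I
f,cy,-0.004845,Davidson (1990) JAWMA 40:1146 Table I
f,az,13.72,Davidson (1990) JAWMA 40:1146 Table I
f,bz,0.6584,Davidson (1990) JAWMA 40:1146 Table I
f,cz,-0.05367,Davidson (1990) JAWMA 40:1146 Table I
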