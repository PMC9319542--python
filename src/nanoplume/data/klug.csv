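# Klug (1969) power-law dispersion coefficients, sigma = R * x**r with x in metres.
# Transcribed from Seinfeld & Pandis, Atmospheric Chemistry and Physics, 2nd ed.,
# Table 18.3 (p. 866).
class,coefficient,value,source
a,Ry,0.469,Seinfeld & Pandis Table 18.3 (Klug 1969)
a,ry,0.903,Seinfeld & Pandis Table 18.3 (Klug 1969)
a,Rz,0.017,Seinfeld & Pandis Table 18.3 (Klug 1969)
a,rz,1.380,Seinfeld & Pandis Table 18.3 (Klug 1969)
b,Ry,0.306,Seinfeld & Pandis Table 18.3 (Klug 1969)
b,ry,0.885,Seinfeld & Pandis Table 18.3 (Klug 1969)
b,Rz,0.072,Seinfeld & Pandis Table 18.3 (Klug 1969)
b,rz,1.021,Seinfeld & Pandis Table 18.3 (Klug 1969)
c,Ry,0.230,Seinfeld & Pandis Table 18.3 (Klug 1969)
c,ry,0.855,Seinfeld & Pandis Table 18.3 (Klug 1969)
c,Rz,0.076,Seinfeld & Pandis Table 18.3 (Klug 1969)
c,rz,0.879,Seinfeld & Pandis Table 18.3 (Klug 1969)
d,Ry,0.219,Seinfeld & Pandis Table 18.3 (Klug 1969)
d,ry,0.764,Seinfeld & Pandis Table 18.3 (Klug 1969)
d,Rz,0.140,Seinfeld & Pandis Table 18.3 (Klug 1969)
d,rz,0.727,Seinfeld & Pandis Table 18.3 (Klug 1969)
e,Ry,0.237,Seinfeld & Pandis Table 18.3 (Klug 1969)
e,ry,0.691,Seinfeld & Pandis Table 18.3 (Klug 1969)
e,Rz,0.217,Seinfeld & Pandis Table 18.3 (Klug 1969)
e,rz,0.610,Seinfeld & Pandis Table 18.3 (Klug 1969)
f,Ry,0.273,Seinfeld & Pandis Table 18.3 (Klug 1969)
f,ry,0.594,Seinfeld & Pandis Table 18.3 (Klug 1969)
f,Rz,0.262,Seinfeld & Pandis Table 18.3 (Klug 1969)
f,rz,0.500,Seinfeld & Pandis Table 18.3 (Klug 1969)
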