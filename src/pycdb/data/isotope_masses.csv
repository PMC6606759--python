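element,isotope_label,exact_mass_da
H,1H,1.00782503
C,12C,12.00000000
N,14N,14.00307401
O,16O,15.99491462
S,32S,31.97207117
Se,80Se,79.91652176
Ag,107Ag,106.90509682
Ca,40Ca,39.96259086
Cd,114Cd,113.90336509
Co,59Co,58.93319429
Cu,63Cu,62.92959772
Fe,56Fe,55.93493633
Hg,202Hg,201.97064340
Mg,24Mg,23.98504170
Mn,55Mn,54.93804391
Ni,58Ni,57.93534241
Pb,208Pb,207.97665248
Zn,64Zn,63.92914201
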