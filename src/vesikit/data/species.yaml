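# Registry of supported lipid species: species name -> moleculetype in
# martini_lipids.itp.  Beads whose name starts with "D" are the cis
# unsaturated sites (C3 bead type, 120 degree kink angle).
DPPC: DPPC
DOPC: DOPC
POPC: POPC
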