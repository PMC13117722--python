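; vesikit packaged force-field subset: MARTINI 2.x phosphatidylcholines + water.
; Twelve-bead PC mapping: 1 NC3 (+1e), 2 PO4 (-1e), 3-4 glycerol, 5-8 tail A,
; 9-12 tail B.  Unsaturated (cis) beads carry a D* name and the C3 bead type;
; the angle centred on them is 120 deg / 45 kJ/mol instead of 180 / 25.
; Nonbonded pairs use the published interaction-level ladder
; (O=5.6, I=5.0, II=4.5, III=4.0, IV=3.5, VI=2.7, VII=2.3, VIII=2.0 kJ/mol;
; sigma 0.47 nm except charged-apolar pairs at 0.62 nm).

[ defaults ]
; nbfunc comb-rule
  1      2

[ atomtypes ]
; name  mass    charge  ptype  sigma  epsilon
  Q0    72.0    0.0     A      0.0    0.0
  Qa    72.0    0.0     A      0.0    0.0
  Na    72.0    0.0     A      0.0    0.0
  C1    72.0    0.0     A      0.0    0.0
  C3    72.0    0.0     A      0.0    0.0
  P4    72.0    0.0     A      0.0    0.0

[ nonbond_params ]
; i   j    func  sigma(nm)  epsilon(kJ/mol)
  P4  P4   1     0.47       5.0
  P4  Q0   1     0.47       5.6
  P4  Qa   1     0.47       5.6
  P4  Na   1     0.47       4.0
  P4  C1   1     0.47       2.0
  P4  C3   1     0.47       2.3
  Q0  Q0   1     0.47       3.5
  Q0  Qa   1     0.47       4.5
  Qa  Qa   1     0.47       5.0
  Q0  Na   1     0.47       4.0
  Qa  Na   1     0.47       4.0
  Q0  C1   1     0.62       2.0
  Qa  C1   1     0.62       2.0
  Q0  C3   1     0.62       2.0
  Qa  C3   1     0.62       2.0
  Na  Na   1     0.47       4.0
  Na  C1   1     0.47       2.7
  Na  C3   1     0.47       2.7
  C1  C1   1     0.47       3.5
  C1  C3   1     0.47       3.5
  C3  C3   1     0.47       3.5

[ moleculetype ]
; name  nrexcl
  DPPC  1

[ atoms ]
; id  type  resnr  residue  atom  cgnr  charge
  1   Q0    1      DPPC     NC3   1      1.0
  2   Qa    1      DPPC     PO4   2     -1.0
  3   Na    1      DPPC     GL1   3      0.0
  4   Na    1      DPPC     GL2   4      0.0
  5   C1    1      DPPC     C1A   5      0.0
  6   C1    1      DPPC     C2A   6      0.0
  7   C1    1      DPPC     C3A   7      0.0
  8   C1    1      DPPC     C4A   8      0.0
  9   C1    1      DPPC     C1B   9      0.0
  10  C1    1      DPPC     C2B   10     0.0
  11  C1    1      DPPC     C3B   11     0.0
  12  C1    1      DPPC     C4B   12     0.0

[ bonds ]
; i  j  func  b0(nm)  kb(kJ/mol/nm2)
  1  2  1     0.47    1250
  2  3  1     0.47    1250
  3  4  1     0.37    1250
  3  5  1     0.47    1250
  5  6  1     0.47    1250
  6  7  1     0.47    1250
  7  8  1     0.47    1250
  4  9  1     0.47    1250
  9  10 1     0.47    1250
  10 11 1     0.47    1250
  11 12 1     0.47    1250

[ angles ]
; i  j  k  func  theta0(deg)  ktheta(kJ/mol)
  2  3  4  2     120.0        25.0
  2  3  5  2     180.0        25.0
  3  5  6  2     180.0        25.0
  5  6  7  2     180.0        25.0
  6  7  8  2     180.0        25.0
  4  9  10 2     180.0        25.0
  9  10 11 2     180.0        25.0
  10 11 12 2     180.0        25.0

[ moleculetype ]
; name  nrexcl
  DOPC  1

[ atoms ]
; id  type  resnr  residue  atom  cgnr  charge
  1   Q0    1      DOPC     NC3   1      1.0
  2   Qa    1      DOPC     PO4   2     -1.0
  3   Na    1      DOPC     GL1   3      0.0
  4   Na    1      DOPC     GL2   4      0.0
  5   C1    1      DOPC     C1A   5      0.0
  6   C1    1      DOPC     C2A   6      0.0
  7   C3    1      DOPC     D3A   7      0.0
  8   C1    1      DOPC     C4A   8      0.0
  9   C1    1      DOPC     C1B   9      0.0
  10  C1    1      DOPC     C2B   10     0.0
  11  C3    1      DOPC     D3B   11     0.0
  12  C1    1      DOPC     C4B   12     0.0

[ bonds ]
; i  j  func  b0(nm)  kb(kJ/mol/nm2)
  1  2  1     0.47    1250
  2  3  1     0.47    1250
  3  4  1     0.37    1250
  3  5  1     0.47    1250
  5  6  1     0.47    1250
  6  7  1     0.47    1250
  7  8  1     0.47    1250
  4  9  1     0.47    1250
  9  10 1     0.47    1250
  10 11 1     0.47    1250
  11 12 1     0.47    1250

[ angles ]
; i  j  k  func  theta0(deg)  ktheta(kJ/mol)
  2  3  4  2     120.0        25.0
  2  3  5  2     180.0        25.0
  3  5  6  2     180.0        25.0
  5  6  7  2     180.0        25.0
  6  7  8  2     120.0        45.0
  4  9  10 2     180.0        25.0
  9  10 11 2     180.0        25.0
  10 11 12 2     120.0        45.0

[ moleculetype ]
; name  nrexcl
  POPC  1

[ atoms ]
; id  type  resnr  residue  atom  cgnr  charge
  1   Q0    1      POPC     NC3   1      1.0
  2   Qa    1      POPC     PO4   2     -1.0
  3   Na    1      POPC     GL1   3      0.0
  4   Na    1      POPC     GL2   4      0.0
  5   C1    1      POPC     C1A   5      0.0
  6   C1    1      POPC     C2A   6      0.0
  7   C1    1      POPC     C3A   7      0.0
  8   C1    1      POPC     C4A   8      0.0
  9   C1    1      POPC     C1B   9      0.0
  10  C1    1      POPC     C2B   10     0.0
  11  C3    1      POPC     D3B   11     0.0
  12  C1    1      POPC     C4B   12     0.0

[ bonds ]
; i  j  func  b0(nm)  kb(kJ/mol/nm2)
  1  2  1     0.47    1250
  2  3  1     0.47    1250
  3  4  1     0.37    1250
  3  5  1     0.47    1250
  5  6  1     0.47    1250
  6  7  1     0.47    1250
  7  8  1     0.47    1250
  4  9  1     0.47    1250
  9  10 1     0.47    1250
  10 11 1     0.47    1250
  11 12 1     0.47    1250

[ angles ]
; i  j  k  func  theta0(deg)  ktheta(kJ/mol)
  2  3  4  2     120.0        25.0
  2  3  5  2     180.0        25.0
  3  5  6  2     180.0        25.0
  5  6  7  2     180.0        25.0
  6  7  8  2     180.0        25.0
  4  9  10 2     180.0        25.0
  9  10 11 2     180.0        25.0
  10 11 12 2     120.0        45.0

[ moleculetype ]
; name  nrexcl
  W     1

[ atoms ]
; id  type  resnr  residue  atom  cgnr  charge
  1   P4    1      W        W     1      0.0
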