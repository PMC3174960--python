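REMARK   2 RESOLUTION.    1.20 ANGSTROMS.
REMARK   3   R VALUE            (WORKING SET) : 0.154
CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1                      
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 15.00           N  
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 15.00           C  
ATOM      3  C   ALA A   1       2.009   1.422   0.000  1.00 15.00           C  
ATOM      4  O   ALA A   1       2.923   1.744   0.760  1.00 15.00           O  
ATOM      5  N   SER A   2       1.436   2.274  -0.843  1.00 16.00           N  
ATOM      6  CA  SER A   2       1.839   3.673  -0.912  1.00 16.00           C  
ATOM      7  C   SER A   2       1.637   4.372   0.429  1.00 16.00           C  
ATOM      8  O   SER A   2       2.515   5.093   0.903  1.00 16.00           O  
ATOM      9  N   LEU A   3       0.482   4.137   1.044  1.00 17.00           N  
ATOM     10  CA  LEU A   3       0.181   4.708   2.351  1.00 17.00           C  
ATOM     11  C   LEU A   3       1.194   4.256   3.398  1.00 17.00           C  
ATOM     12  O   LEU A   3       1.144   4.610   4.576  1.00 17.00           O  
TER      13      LEU A   3                                                      
END                                                                             
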