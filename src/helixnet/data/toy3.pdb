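TITLE     MDANALYSIS FRAME 0: Created by PDBWriter
CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1
REMARK     285 UNITARY VALUES FOR THE UNIT CELL AUTOMATICALLY SET
REMARK     285 BY MDANALYSIS PDBWRITER BECAUSE UNIT CELL INFORMATION
REMARK     285 WAS MISSING.
REMARK     285 PROTEIN DATA BANK CONVENTIONS REQUIRE THAT
REMARK     285 CRYST1 RECORD IS INCLUDED, BUT THE VALUES ON
REMARK     285 THIS RECORD ARE MEANINGLESS.
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00      A    N  
ATOM      2  CA  GLY A   1       1.460   0.000   0.000  1.00  0.00      A    C  
ATOM      3  C   GLY A   1       2.100   1.300   0.200  1.00  0.00      A    C  
ATOM      4  O   GLY A   1       1.500   2.300   0.500  1.00  0.00      A    O  
ATOM      5  N   ALA A   2       3.400   1.300   0.100  1.00  0.00      A    N  
ATOM      6  CA  ALA A   2       4.200   2.500   0.300  1.00  0.00      A    C  
ATOM      7  C   ALA A   2       5.600   2.200   0.800  1.00  0.00      A    C  
ATOM      8  O   ALA A   2       6.000   1.100   1.200  1.00  0.00      A    O  
ATOM      9  CB  ALA A   2       4.300   3.300  -1.000  1.00  0.00      A    C  
ATOM     10  N   SER A   3       6.400   3.200   0.800  1.00  0.00      A    N  
ATOM     11  CA  SER A   3       7.800   3.100   1.300  1.00  0.00      A    C  
ATOM     12  C   SER A   3       8.600   4.400   1.200  1.00  0.00      A    C  
ATOM     13  O   SER A   3       8.100   5.500   1.000  1.00  0.00      A    O  
ATOM     14  CB  SER A   3       8.500   2.000   0.500  1.00  0.00      A    C  
ATOM     15  OG  SER A   3       8.000   0.800   1.000  1.00  0.00      A    O  
END
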