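HEADER    SYNTHETIC CA TRACE FIXTURE
ATOM      1  CA  ALA A   1      11.104  13.207  10.567  1.00 10.00           C
ATOM      2  CA  GLY A   2      14.512  11.887  11.003  1.00 10.00           C
ATOM      3  CA  SER A   3      17.200  13.451  12.890  1.00 10.00           C
ATOM      4  CA  LEU A   4      18.901  16.754  12.102  1.00 10.00           C
ATOM      5  CA  VAL A   5      21.003  17.902  15.110  1.00 10.00           C
TER
END
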