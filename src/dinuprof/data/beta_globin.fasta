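>Human U01317 beta-globin exon-1 CDS
ATGGTGCACCTGACTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAGGTGAAC
GTGGATGAAGTTGGTGGTGAGGCCCTGGGCAG
>Chimpanzee X02345 beta-globin exon-1 CDS
ATGGTGCACCTGACTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAGGTGAAC
GTGGATGAAGTTGGTGGTGAGGCCCTGGGCAGGTTGGTATCAAGG
>Gorilla X61109 beta-globin exon-1 CDS
ATGGTGCACCTGACTCCTGAGGAGAAGTCTGCCGTTACTGCCCTGTGGGGCAAGGTGAAC
GTGGATGAAGTTGGTGGTGAGGCCCTGGGCAGG
>Lemur M15734 beta-globin exon-1 CDS
ATGACTTTGCTGAGTGCTGAGGAGAATGCTCATGTCACCTCTCTGTGGGGCAAGGTGGAT
GTAGAGAAAGTTGGTGGCGAGGCCTTGGGCAG
>Rat X06701 beta-globin exon-1 CDS
ATGGTGCACCTAACTGATGCTGAGAAGGCTACTGTTAGTGGCCTGTGGGGAAAGGTGAAC
CCTGATAATGTTGGCGCTGAGGCCCTGGGCAG
>Mouse V00722 beta-globin exon-1 CDS
ATGGTGCACCTGACTGATGCTGAGAAGTCTGCTGTCTCTTGCCTGTGGGCAAAGGTGAAC
CCCGATGAAGTTGGTGGTGAGGCCCTGGGCAGG
>Rabbit V00882 beta-globin exon-1 CDS
ATGGTGCATCTGTCCAGTGAGGAGAAGTCTGCGGTCACTGCCCTGTGGGGCAAGGTGAAT
GTGGAAGAAGTTGGTGGTGAGGCCCTGGGCAG
>Goat M15387 beta-globin exon-1 CDS
ATGCTGACTGCTGAGGAGAAGGCTGCCGTCACCGGCTTCTGGGGCAAGGTGAAAGTGGAT
GAAGTTGGTGCTGAGGCCCTGGGCAG
>Bovine X00376 beta-globin exon-1 CDS
ATGCTGACTGCTGAGGAGAAGGCTGCCGTCACCGCCTTTTGGGGCAAGGTGAAAGTGGAT
GAAGTTGGTGGTGAGGCCCTGGGCAG
>Opossum J03643 beta-globin exon-1 CDS
ATGGTGCACTTGACTTCTGAGGAGAAGAACTGCATCACTACCATCTGGTCTAAGGTGCAG
GTTGACCAGACTGGTGGTGAGGCCCTTGGCAG
>Gallus V00409 beta-globin exon-1 CDS
ATGGTGCACTGGACTGCTGAGGAGAAGCAGCTCATCACCGGCCTCTGGGGCAAGGTCAAT
GTGGCCGAATGTGGGGCCGAAGCCCTGGCCAG
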