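>host_F|EF1a|anc
CGGACTGAATTCATGCGCACTGCCCTAGGACAACAACTCTTAAAGCATAGATTCGTATCA
AACTAAGCTTGGCACAACCTCGCTGGCTATTCGCCTGTCGGACCCTCCAGTAAATTATGA
GCCCACGTGGCGAACCCACTTCTATGCCGACCAAAATCATTGTCCTGTGTCGGTCTTGGA
ATAGAGGATACTGGGGGCCGAGGTCAGTAACTGATCAAGGTAGATCCGGAAACTGAGGAC
GTCCGATAGGTGACGCCTACCGTTAAGGAGCAAGCTTGGGTCAAAGAAAAAGGAACCCGT
AAAAAAAAAGGTATACGTTCGGTCTCAGACGATCCGAAAAGTTTTGGGAACAAAGCGGCG
ATGTATCCATCGACAACAGACTTCTTTTCCGGTGGTCGTGCGGATAGCGGGCGCACAATC
CTCAGGCGGACACTCCTAACTGCTAATATA
>host_F|COI|F
GCATGTTGGCAGGCGGTTCAGCCGAATAAGGCCAACTCTACAAGGAGATTCCAGTGGGTA
GCGCTCCGTATGATAGCCTGGATTAAGCGCCCGTCGGACGCGTACTTTCCAAACTAGTGG
GCAGCGCACTCAACCTCGATCTATGGACAGCGTAGGGCGGCCGCTGCAAAAGTCGATCGC
GGCCCTCACGCAAGGGTGATCCCCCTTTTTATAGATTCACTTGGCCCCATGGTAATACCC
TGATCCTTCGTGGCGTCGTGGTTCGTCGTGGAGGCTGCTTTTGTGAACCACGAACGTTGT
GGAGGCAATCTTGTTCAGCGAAAGGTGTCTCGAGCTCAAATTGCTCCCCAAACAGAACAC
TATCAGCAAAGCATATGAACTTTAATCTGGCCGTAGATAAAGCTCATTGAGCTTTACCCA
CTGACTCTCGCGCGTTTTGGGGCAGCAAGATGAGCGAATCGTCGAGTCCGGTAATTCATG
AGAAGAATATTAGGATATCTGCTATGCATGCTTTAGTGCTCCGTGATTTGCGTACTCACT
TCATCTCACAACAGCCCGCAATCCTGAGTTGCTAATGAAAGTAAGAGCTATAAGGTGGAG
TAGAGCATGCTTAGGCAGCCCCGCCATAAG
>host_F|CR|F
GGCGCTAGACAGTAGGACCTTACCCAGGTCAACGTCCCAACTACAGCAGGTGCATATTGC
ACATGTCTACAAACGAGTTGTTGGATAACGGCGCACTCGCATGCCATGGCGCAAGGTTAA
GGTTACACCGCAGCAGTAGTACCGTGTCGATGATGCTCCTTATATGATCGACGGGTATAA
ATTTCTGGTGGGATCCCACTTAGTAACCCGACAGTCCATTAATCCTTGACCGCCCGCGAT
ATCCGGCGAACGTGGGAACGCTCTGCGAGTCAAGTTACCCAGTTCACGTAAGCCGCGTTA
TCGGAGTTTCATGGTGATAGCAGGGGGTTGAAAAGAAGCTGCGTCATAGACGCGACCACC
TCTGGACTAGTCTACTGGACTCGCCTCTATCGGTTGGCGAGGTATACTTGGCTTGGACAT
TTCCATTGCCTAAGAGCTCAAGCCGCACCGCGTTTGGATCGCTGTTGCTCGGTTGTGAAA
ACGGGTACTCGACACTGGATGAAAACGGGACCCCATTGGCGAAGCTAGTAATAGTCGTCC
GGCTATCCTGTGGGGTCACTATTCATGGTGCACGGCCTCGGGGACATTTAGGTAAGCATG
GGCCGCTCGCGGTTACCGAGCG
>host_F|16S|F
AAGGTTACGAACTGTCGTTCTGGAAGTATGAAAGCCTCATCAGTAGAACAGGTTTTCACT
AGACTTTCAACTACTATAAGACCGAGGCGGTTAATCCATCTAGCACTAAGTTCCGGCTGA
TAATACGTCCTGATTAGGCGAAGCATATTGTCAGGGATTCATCTGTCGATCCCGCCCACC
AGCAAGGTCCCTGAAGTGCAGCAGATGCTTAATGGTCGGGACTATGGTCCTTATTCAAGA
TTGATGCGGCATTTGGCCGCCTGGCTGGGGTTCAAACGTGCTGAGTAGCTGAGTTCAAAA
TTATTACGCCCCCTGGCCCAACTCTCGTTCATGTTCCGTACTTCTTCGTAAGATTATCAC
AGCCTGTGCAGCCTGTGGCCACGGAGATTAGCGGACCGCCCACGTCGCGTCTGGATGGCT
ATGGAGCGCATGCCGGGCGCGATTAGGCGAAGTTATCCCCGGCAGGTGTCGATTTACATT
GCTCAAAGATTCGCTTATTA
>host_M|CR|M
GGCGCTAGACAGCAGGACGTTACCCAGGTCAACGTCCCAACTACAGCAGGTGCATATTGC
CCATGTCTACTAACGAGTTGTTGGATAACGGCTCACTCGCATGCCATGGCGCAAGGTTAA
GGTTACACCACAGCAGTAGTACCGTGTCGATGATTCTCCTTATATGATCGACGGGTATAA
ATTAGTGGTGGGATCGCACTTAGAAACCCGACACTACTTTAATCCTTGACCGCCCGCGAT
ATCAGGCGAACGTGGGAACGCTCTGCGAGTCAAGCTACCTAGTTCACGCAAGCAGCGGTA
TCGGAGTTTCATGGTGATAGCAGGGGGTTGAAAAGAACTTTCATCATAGACGCGACCAGC
TCTGGACTAGTCTACCTGACTCGCCTCTATCGGGTGGCGAGATATACTTGGCTTGTACAT
TTCCATTGCCTAAGACCTCAAGCCTCTCCGCGTTTGGATCGCTGTTGCTCCGTTGTGAGA
ACGGGTACTCGACGTTGGATGAGAGCCGGACCACATTGGCGCAGCTCGTCATAGTAGTCC
GGCTATCCTGTGGGGTCACTATTCGTGGTGCACGGCCTCGGGGAGATTTCGATCAGCATG
GGCCGCTCGCGGTTACCGAGCG
>host_M|16S|M
AAGGTTACGAACTGGCGTTCTTGAAGTATGAAAGCCTAATCAGTACAACAGGTATTCACT
AGACTTTCCACTACTATAAGACCGAGGCGGTTAATCCTTCTAGCACTAAGTTCCGGCTGA
TAATACGTCTTAATTAGGAGAATCAAATTGTCAGGGATTCATCTGTCGAGCCCGCCGACA
AGCAAGGTCCCTGAAGTGCAGCAGATGGTTAATGGTCGGGTCTATGGTCCTTCTTCAGGA
TTGATGCTGGATGTGGCCGCCTTGCTGGGGTTCAAACGAGCTGAGTAGATGAGTTCAAAA
TTATTACGGCCCCTGGACCAACTCTCTTTCATGTTCCGTACTTCTTGGTAAGCTTATCAC
AGCCTGTGCAGCCTGTGGCCTCGGAGATTAGCGGACCGCCCACGTCGCGCCTGGATGGTT
ATGGAGCGCATGCCGGGCGCGATCAGGCGGAGTTATCCCCGGTAGGTGTACATTTACATT
GCTAAAAGATTCGCTTATCA
>BTN2|EF1a|G
CGGACTGAATTTATGCGCACTTCCCTAGGACAACAACTCTTAAAGCATAGATTCGTATCA
AACTAAGCTTAGCACAACCGCGCTGGCTATTCGCCTGTCGGAACCTCCAGTAAATTATGA
GCCCACGTGGCGAACCCACTTCTATGCCGACCAAAATCATTGTCCTGTGTCGGTCCTGGA
ATAGAGGATACTGGGGGCCGAGGTTAGTAACTGATCAAGGTAGATCCGGAAACTGAGGAC
GTCCGATAGGTGACACCTACCGTTAAGGAGCAAGCTTGGGTCAAAGAAAAAGGAACCCGT
AAAAAAAAAGGTATACGTTCGGTCTCAGACGATCCGAAAAGTTTTGGGAACAAAGCGGCG
ATGTGTCCATCGCCAACAGACTTCTTTTCCGGTGGTCGTGCGGATAGCGGGCGCACAATC
CTCAGGCGGACACTGCTAACTGCTGATATA
>BTN2|EF1a|H
CAGACTGAATTTATGCGCACTTCCCTAGGACAACAACTCTTAAAGCATAGATTCGTATCA
TACTAAGATTAGCACAACCACGCTGGCTATTCGCCTGTCGGTACCTCGAGTAAATTATGA
GCCCACGTGGCTAACCCACTTCTATTTCGACCAAAATCATTGTCCTGTGTCGGTCCTGGA
ATAGAGGATACTGGGGGCCGAGGTAAGTAACTGATCAAGGAAGAACCGGAAACTGAGGAT
GTCCGATAGGTGACACCTACCGTTAAGGAGCAAGCTTGGGTCAAAGAAAAAGGAACCCGT
AAAAAAAATGGTATAAGTACGGTCTCATACGATCCGAAAAGTTTTGAGAACAAAGCGGCG
ATGTGTCCATCGCCAACAGACTTCTTTTCCGGTGGTCGTCCGGATAGCAGGCGCACAATC
CGCAGGCGGACACTGCTAACTGCTGATATA
>BTN2|COI|B
GCATGTTGGAAGGCGGTTCAGCCGAATAAGGCCAACTCTACAAGGAGATTCCAGTGGGTA
GCGCTCCGTATGATAGCCTGGATTAAGCGCCCGTCGGACGCGTACTTTCCAAACTAGAGG
GCAGCGCACTCAACCTCGATCTATGGACAGCGTAGGGCGGCGGCTGCAAAAATCGATCGC
GGCCCTCACGCAAGGGTGATCCCCCTTTTTATAGATTCACTTGGCCCCATGGTAATACCC
TGATCCTTCGTGGCGTCGTGGTTCGTCGTGGAGGCTGCTTTTGTGAACCACGAACGTTGT
GGAGGCAATCTTGTTCAGCGAAAGGTGTCTCGAGCTCAAATTGCTCCCCAAACAGAACAC
TATCAGCAAAGCATATGAACTTTAATCTGGCCGTAGATAAAGCTCATTGAGCTTTACCCA
CTGACTCTCGCGCGTTTTGGGGCAGCAAGATGAGCGAATCGTCGAGTCCGGTAATTCATG
AGAAGAATATCAGGATATCTGCTATGCATGCTTTAGTGCTCCGTGATTTGCGTACTCACT
TCATCTCACAACAGCCCGCAATCCTGAGTTGCTAATGAAAGTAAGAGCTATAAGGTGGAG
TAGAGCATGCTTAGGCAGCCCCGCCATAAG
>BTN2|CR|D
GGCGCTAGACAGTAGGACCTTACCCAGGTCAACGTCCCAACTACAGCAGGTGCATATTGC
ACATGTCTACAAACGAGTTGTTGGATAACGGCGCACTCGCATGCCATGGCGCAAGGTTAA
GGTTACACCGCAGCAGTAGTACCGTGTCGATGATGCTCCTTATATGATCGACGGGTATAA
ATTTCTGGTGGGATCCCACTTAGAAACCCGACACTACTTTAATCCTTGACCGCCCGCGAT
ATCAGGCGAACGTGGGAACGCTCTGCGAGTCAAGCTACCTAGTTCACGCAAGCAGCGGTA
TCGGAGTTTCATGGTGATAGCAGGGGGTTGAAAAGAACTTTCATCATAGACGCGACCAGC
TCTGGACTAGTCTACCTGACTCGCCTCTATCGGGTGGCGAGGTATACTTGGCTTGGACAT
TTCCATTGCCTAAGAGCTCAAGCCGCACCGCGTTTGGATCGCTGTAGCTCGGTTGTGAAA
ACGGGTACTCGACACTGGATGAAAACGGGACCCCATTGGCGAAGCTATTAATAGTCGTCC
GGCTATCCTGTGGGGTCACTATTCATGGTGCACGGCCTCGGGGACATTTAGGTAAGCATG
GGCCGCTCGCGGTTACCGAGCG
>BTN2|CR|C
GGCGCTAGACAGTAGGCCCTTACCCAGGTCAACGTCCCAACTACAGCAGGTGCATATTGC
ACATGTCTACAAACGAGTTGTTGGATAACGGCGCACTCGCATGCCATGGCGCAAGGTTAA
GGTTACACCGCAGCAGTAGTACCGTGTCGATGATTCTCCTTATATGATCGACGGGTATAA
ATTTCTGGTGGGATCCCACTTAGAAACCCGACACTACTTTAATCCTTGACCGCCCGCGAT
ATCAGGCGAACGTGGGAACGCTCTGCGAGTCAAGCTACCTAGTTCACGCAAGCAGCGGTA
GCGGAGTTTCATGGTGATAGCAGGGGGTTGAAAAGAACTTTCATCATAGACGCGACCAGC
TCTGGACTAGTCTACCTGACTCGCCTCTATCGGGTGGCGAGGTATACTTGGCTTGGACAT
TTCCATTGCCTAAGACCTCAAGCCGCACCGCGTTTGGATCGCTGTTGCTCGGTTGTGAGA
ACGGGTACTCGACACTGGATGAAAACGGGACCCCATTGGCGAAGCTAGTAATAGTCGTCC
GGCTATCCTGTGGGGTCACTATTCATGGTGCACGGCCTCGGGGACATTTAGGTAAGCATG
GGCCGCTCGCGGTTACCGAGCG
>BTN1|EF1a|A1
GGCACTGAATACGTGCTCTCTGCCCTAGGACAACAACTATTAAACCATAGATTCGTATCA
AACTAAGCATGGCACAACCTCTCTGGATATTCGCCTGTCGGACCCTCCAGTAAATTATGA
GTCCACGTGGCGAACCCACTTCTATGCCGACCAAAATAATTGTCCTGTGTCGGTCTTGGA
ATAGAGGATACTGGGGGACGAGGACAGCAACTGATCAAGGTAGATCCTGAAACTGAGGAC
GCCCGATAGTTGGCGCATACCGTTAAGGAGCAAGCTGGGGTCAAAGAAAAAGCAACCCGT
AAAAAACAAGGTATACGTTCGGTCTCAGACGATCCGAAAAGTTTTGGGAACAAAGCGGCG
ATGTATCCATTGACAACAGGCTTCTTTTTCGGTGGTCTTGCGGATAGCGGGCCCACAATC
CTCAGCCGGACACTCCTAACTGCTAATATA
>BTN1|COI|A
GCATGTTGGCAGGCCGTGCATCCGAATAAGGCCAACTCTACAAGGAGATTCCAGTGGGTA
GCGCTCCGTATGATAGCCTGGATTAAGCCCCCGTCGGACGCGTACTTTCCAAACTAGTGC
GCAGCGCACTCAACCTCGATCCATGGACAGCGTAGGGCGGCCGCTGCAAAAGTCGATCGC
GGCCCTCACGCAAGGGTGAGCCCCCTTTTTATAGATGCACTTGGCCCGATGGTAATACCC
TGATTCTTCGTGGCGTCGTGCTTCGTCGTGGAGGCTGCTTTTGTGAACCACGAACTTTGT
GGAGGCAATCTTGTTCAGCGAAAGGTGTCTCGAGCTCAAATTGGGCCCCAAACAGAACAC
TATCAGCAATGCATATGAACTTTAATCTGGCCGTAGCTAAAGCTCATTGAGCTTTACCCC
CTGACTCTCGCGCGTTTTGGGGCAACAAGATGAGCGAATCGTCTAGTCCGGTAATTTATG
ACAAGAATATTAGGATATCTGCTATGCATGCTTTAGTGCTCCGTGATTTTCGTACTCACT
TCATCTCAGAACAGCCCGCAATCCTGAGTTGCTAATGAAAGTAAGAGCTATAAGGTGGAC
TAGAGCATGCTTAGGCAGCCCCGCAATAAG
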