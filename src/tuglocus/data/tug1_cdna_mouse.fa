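>Tug1_cDNA_mouse ENSMUST00000153313.2 cDNA clone (as published)
TTTTTTTTTTTTTTTTTTTTTTTTTTTTTGGGGGGGTTTTTTGTTTTGTTTTTTAAATTGAAGGCTAAAG
TTTTTGAAAAAACTTTGTTGGACTCTGGCTGGGACACAAAATCAGATATTTGGAATCATTTTGAAGCTTA
ACTTTTTCCTAACCAGCCTTGTATTCTAATTGCTTGCAAATGTGAGACTGAATGGCCAAAATGCCGTTTG
TTTGTTTGTTTATTGTCAGCTGCTTTTATCAAATTCCAGGCCATTATCCAGCAAACACTATTAAAATGTT
TGAACAGTTGGGTTTCAAACATTTTTGTTTTGTGGAGTGGTGCTTATTAAGTGGTACAGCTCTCTAAGCA
AGTGAACACAAACATATTTAAGTGTATTTTGTATGATTAGATGTTACCAATTCTGATATTTTATTCAAAT
GTCTAAAAAAATAAGTTGACTTATTCCCTTTACCAAAGGGCCAGAGACAAATGGTTTCCTTTCAAGAGAA
ATGACTGTTTTGAAGAAAAACTCTGTTGGTCTTAGCTCTTTTGTAATTAAATCTGGATGTACCTCAAAAG
ACTCTTTAAGACTGTGGTGTTAAAAGGCTTTCCTCTGGAGAAGGAGAAAAAATAAAATCAACTGGAACTT
AAAAGCTTGAAATTCCATGACAAAACACAGATGTCCAGGATTGGAGGTTCATAAAGTACATGCAGTAGTT
GGAGTGGATTCCATTTTCAGTGTAGCTGCCACCATGGACTCCAGGCTCCCAGATTTTCAAGAACTGGACC
TGTGACCCAGAAGAGCTTGTCAAGATATGACAGGAACTCTGGAGGTGGACGTTTTGTATTCAATTTTGGA
ACTGTTGATCTTGCCGTGAGAAAAGAGAGACACGACTCACCAAGCACTGCCACCAGCACTGTCACTGGGA
ACTTGAAGATCCAAGTTTCTGTCCAGAACCTCAGTGCAAACTGACAACACTCCATCCAAAGTGAACTACG
TCCCGTGCCTCCTGATTGCTGAATGTTCACCTGGACCTGCCAATGACCTTCCTTCTGCTACTCCATCAGC
CTACAGACCTGGTACTTGGATTTTTGTCCATGGTGATTCCTTCCACCTTACTACTGAAGAAGACACCATT
CCAGTGGACCACTGTGACCCAAGAAGCATTCAGCCATCATGATGTGGCCTTTACCTCCACTCCTGTCCTA
CTCTGCCCAGATTCAGCACAGCCCTTTATAGTGCAGTCAAGAGTCTTCAAGCCAAATAACTGAAGCTATT
TTATCACAACAAAGGCCAGGTTTATTCCATAAATGTACAGTTCATTTCTGCAGTTTATTCTTCAGAGACA
CATAGTAAATTTGGACCAGGGGATTTTGTTTTGTTTATATTGTCAACACTGTCTGAAGAAAGGCATCTCT
GAGAACAGCATTGGACCCTACTCCACAATCTCAAATGATTGAAGTTTCATAAACTGCCTAGGATCCTGTC
AAGGCCACTGGACTCTTGTTCTTTTCCTACTTCAAAATCTGTAGCTGTCTACTAAATGACAAAGCAGATA
TTCTGACCCATTGGGATCAAAACCAAGGCATTTTGAATTCCTCATAGTATCATCTTCGGGTTACTCAGGA
ACCAAAACTTTTCACACCAATTTAAGAAATTCTACTGAGGAATCCCTTTACCTAACCATCTCACAAGGCT
TCAACCAGATTCCTGAAAAGGCCTCTTGATATATCAAGATAGAACCTACATGCATTTTGTGAACAACTTA
TCACTGATTTTCCAAAGGCTTTGTGCTCTTGAAGTTCTTTGAAGGAAAGCTGTGTGGAAGTCCAGAGTAA
AGTGAAGCTGCTCTGGATGAAGTAGTGAAGTGGGAGTTGAGGTCTACAACCTGCCACAACCATCTTCCTT
TACCACCATGGTGATGCCAAAAGGGACTTCCTTAAAGCTCTTCAGAAAATCCTGCTTGAAACCACTACCC
TAGACAACATGTTTGACCTGGATGGCATTCTCTTCAAAACAATTCATATTCAGTTGATGCTCAACATGTT
TGGAGATGCTTTATTCAGAGAATGATGATAATTACAGCATTGTCTAATGAAGTTTTATTAATAGCATTCC
ATCCAAGGTGGACTTCCTGGAGTTGGATATAACCAGAGAGCAATTCATATGTATCCTACACTGAAGAACA
CCATTAACTTTCAGCAACCTATAGCTAGTGGTACTAGAAGTACGTGTCTTGGAAGTCTATGAGAGCTGGT
ATTGAAGCTGATGCCTCCTTAAGGCCATCTTAGACCAAGTTGTTTGTTTGACCTCTCCTCATTAACTATG
GAGCAGAATTGAAATACAAATTTTTCCTAAAGGGACTTGCAACCTGGTTATCATTCATTATCTCAAGTTT
CAAGTCATGTTGATGCAACCAGTAGTTATTAAACTGCTCCATGGTTTTTTGTTATTTAATACTTTTTCCA
GGGCTTAAAAAAACAAAATTAAATTTCTCCAACACGTCTATACTTGTCTGTTCAAAAGTAACTACTCACC
ACTATATGGAACAGATGATTCTGAAGACACTCTGAGCATCCTTTATGATATTTGTGACTTAAAATGTGGC
TGGAAATTTTCCTTCTACCCAGTGAAATATTTAATGATTAGTCTTCATGCCTGATACCATCAACTGTATA
TGCGTGATAGGCAAAGTTTGACATAGGCATTTGACTCTAGGCTATGATAGCTTGCTAGTAACTTCAAGTA
GCATATTGTCAACCTGTTTGCTGGAAAAGTAGAGTAACTTGGAAAAAAAACTAAATGGCAGCTAAGGATT
TTTTTCAGTATTCCTGAGTTTCTGTCCTTGGGATATTTCAATGAAATTTTCACCTGTCTCTTCACTTAAC
AGAGTGACTGACTCCTTACTATGAAGTATTCTTAAGACATTAAGATTACTTTTGTAGAAAGGATAAAATT
CCTGACCATCCAAATCATCATAGTGAACAAGACTTCAATTTGTGACCTGAGAAAATCTCATTTCTCTACT
TCGTAGTCAATGTAAGGGCCAATGCTATCAGCTACTCTGAGTGCACTGGGTAAACGTTGGAACTGCCTTC
TTTATATCATTACTTTTTATCCTCTAAATTAATCATGGTTATGTAATTCTCGCCACAAATCAGCAAATCA
GACTCAGATCTGGTTATTCTAGACTGCTCACAGTTAACAAATCAAACTCTGGATGACTTCTGCTTGTATA
TGCAACTACTATTTGTAAAGAAATTGCAAATTCACTTTTCTATTACCTCTACATTGCTAGCTCTTTCTTT
TGTGTTTGTATTAAAAACAAAAATAAGCTACACTGCCAGCTATTCCCTCCTGCCATACTCAGTTAAAATG
AAGAATCGGGAATCTAACCAGTGAATGGATAAGTAGAAAAAACTAAAACTTAAGGCAAAAGCCTTAATCT
AGGGCCTTTTCTACTATCTTCATGTCTTGGATTTCATCTAAAATCAACAGTGCCACCCAACCAGTCTGAG
GTCTTGACTTGCTTTTAAGATGATTCTTAGAGATGGGCTGTATTACAGAAGGTGAAGACTTGATTACCAA
AGAAAGTAGAGCCAACTTTGACAAACCTGGCTCTACAATCCTATTGCTTCCAGATGTAGCATAGACTCAT
AACTAGAACCTCAAGTCTGCATTGAGGATATAGCCTTCTAAGCTGACAGTTCTTGCAACAGGTGAGCAAG
AAAATGAAAGCTGTTATACCCAACTGGCCCTTTAAGATCCAAAAATAATGTCTGGACTAAACCCTATGGA
GTACCCAGGACAAAAACTAATTTACAGAGCTTCATTATTAATCTGCCTGTTCTTCTAGCTTAATTATTGG
TATGGCTGGCCCTACTGAAGTAGTTTGTCTGTTTACCTGTCTTCAGCTCTTAACCTGGCTATTTTGACAT
GCTACTGCAATTAGACTAACTGGCTTTGAGAAGACTACAATCAGTTTCAGCCTCTCCTTTGCCCAATTTC
ACCAAGGAATTTTGATAAGAGGAACCCATACCTCACCCCACCAGAACAGAAAGGACCATGCTGCATATTC
CTTGACCAGCAACTTTAAGTAGAGAACAACCCTGCTTGTTTTCAACATCTGAAACACCATTTGATCTAAT
AGGAGTATAGAAGGTTGACAGCAGAGTACACTACTTACTTCTTTCATAACTCAGAAATGAATATGACTGG
CCCAGAAGTTGTAAGTTCACCTTGACAAGAAACAGCAACACCAGAAGTTTACTGCTGAACTTAACTTGCC
ACTTACTCGAATAGTCTCACAGACCTGCTTGCCAAGTAGGAGGCTAGTTTTCCTGCTTCATATCACCATT
GGAGTGGGGCTCAATGGGGTCAATGTTAATACTGACTTGAATGGGGACCTTATGGTGAATCCTAGACTAT
GAGGCTAATGGAAATTATTGTCTATTCAAGTGGATTATAGATTTCCTGAGGACAGAACAGACATCACTCC
TGGTGATTTTTAGAACTTGATTACCAAGGAAGAAATACCAGCTGCTAACAGTCAACTTCATGGGCAAAGA
TTAAGCTCTCTATATCTGGTCGTATCCTGGATGCTAGTTTTTTATTGCCCAGTGACCATTTCCATCTCAC
GCTTAACTTCCTGATGTTTTTTGGAACCATCTCTTCCAATTTTCAGTCCTGGTGATTTAGACAGTCTTTT
CATGCTGGACATTTTGTTGCAACCTCATCAATCACAGCAAAGTCCATCTTGACTTTAGTGATTAGTTCAG
GAATGGATGCATGATTCAAGTTTGTCCAATGATAATCAACCCTAGGTGTTTTCTCAGTTGTGGAGAAGTT
CTCTTAGATGCTTTAGCTTTGTAGGAGAAAACTCAAACCAACAGGGCCTACCTACTATGTTGAATGATTG
TAGGAGAAAACTCAAACCAACCAGGCCTACCTACTATGTTGAATGAGCCAGGCAGAAAATGAAGCCAGTA
CAGAGGGAAATGGAGCCAAAAGAGGAAGAGACTTGAGTTCTGATGATCACATTTATGCCCCTGTATCCAA
CTGTGCCTGAAGCTAATAGTACATCACCTGGACTTTTCAGTTATGTGAACCAATAAATTCCCCTTTTTGT
TTAAGTTACTTTGAGTT
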