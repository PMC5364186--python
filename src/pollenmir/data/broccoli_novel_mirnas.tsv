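name	mature_sequence	precursor_mfe_kcal_mol
bol-miR01	GGAATGTTGTTTGGCTCGAAG	-20
bol-miR02	AGATATTAGTGCGGTTCAATC	-44.5
bol-miR03	GGCCGTGGGATGTGGATGGCA	-45.5
bol-miR04	ATGCACTGCCTCTTCCCTGGC	-38.2
bol-miR05	GTTCTTAAAGTAGATCTTCGGAA	-44.7
bol-miR06	AATGAAATAAGAAGGCGAGGATT	-37.3
bol-miR07	TGCATCAACTGAATCGGAGCC	-73.5
bol-miR08	TCTCAAACCGTGATGATGGACG	-30.1
bol-miR09	TCTGAAACTTTGTGACATTGCAG	-57.4
bol-miR10	TAGCTAGTAGATGTTGTCGTG	-22.8
bol-miR11	CTTCGTGTAAATGATTTTCCTT	-33.3
bol-miR12	CAGCGAAGAGGATGTAGCGGAG	-36.1
bol-miR13	AGAACTCATGAGAAGGCTTGGTG	-29.6
bol-miR14	GGAAGACCGGTGAAACTCATCTC	-29.3
bol-miR15	ACCCTTCTCACGCAGATCAAC	-30.7
bol-miR16	GATTGACGACGACGAGGGAGACG	-75.2
bol-miR17	CGGAGGAAACGGGTTCTCGGG	-25.8
bol-miR18	TGGATATGATGAAATGGCATA	-29
bol-miR19	AGGCAGCGAAGTAGGACTGGCTT	-38.4
bol-miR20	GAGGTATGGGACGATGGTGG	-49.7
bol-miR21	GCTTGTCTCTGAGATCCCGGCG	-28.5
bol-miR22	TTGTGCAAGACTAAGAAGCAA	-46.7
bol-miR23	TGGCTAAATCCAGATATGTCG	-43.9
bol-miR24	GCTTCTAGTGCGATCGGGTTCGG	-49.3
bol-miR25	GCCATGGCGGAAGAGTTTTTATC	-36.1
bol-miR26	ACTTGTTTCGTCGGTATGTCG	-51.6
bol-miR27	GACGGTTCTTAGCTTTTCTT	-25.9
bol-miR28	GAGCGACTGTTTCTTCGTCGGA	-56.8
bol-miR29	TAATCATGTTTAGACTTAGATCA	-46.7
bol-miR30	GGACGTGCTGTAGGAGTAACCC	-28.7
bol-miR31	GGAGGATGACGGAGAAGGAGCA	-60.5
bol-miR32	TCTGGTGTAGACGTGGTATC	-48.9
bol-miR33	ACAGCTCTGCTCCATCTGTGA	-85.3
bol-miR34	TGGCTGCTGGAATTGATGGTC	-34.7
bol-miR35	TCCCTTTGGATGTCGTCTTGTG	-30.1
bol-miR36	GTGTTGTTTGACTTGAGATGACG	-44.1
bol-miR37	ACTTCACATTGTGGTCGTCTGA	-37.5
bol-miR38	CCAGATCTGGGATTGGCCAAC	-43.9
bol-miR39	TCTCAGTGGATTTCGAATGGA	-29.6
bol-miR40	CAGCTGTAGAGTGCTGGAAGGA	-25.4
bol-miR41	CGATTGTGGAAGAAAGTGGA	-34.2
bol-miR42	GGAGAGTCGGCGTGGCATCAAG	-71
bol-miR43	AATCGGCTTGTAGCAGTGGCA	-55.2
bol-miR44	CGACAGCTTCTCGTCGGTCGATA	-45
bol-miR45	CTAAGCAGGATCCAAAGACGTT	-28.6
bol-miR46	AGGTGGTTATTGGAGTCGGTTTA	-40.7
bol-miR47	CAAGTTGTAGGTTAGTTTTGGCA	-34.2
bol-miR48	AGGAGACTGTTTATGTAAGGCTA	-28.1
bol-miR49	AGGACTATAGGCGAAGCGGGGTT	-37.8
bol-miR50	CACCCTTCTCACGCAGATCAA	-35.7
bol-miR51	TCCCTTTGGATGTCGTCTTGT	-30.1
bol-miR52	CGTCATTTGGATCCATCGGG	-33.7
bol-miR53	GTGCTTATTGACGGTCTTGT	-32.5
bol-miR54	AGGACTTGTCTTGGATAGGTATA	-29.9
bol-miR55	GTTGGAGGAGGAGGAGGAGGA	-38.8
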