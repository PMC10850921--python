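locus	forward	reverse	core_top	core_bottom	motif	start	end	length	core_source
cpINDEL1	GTTCGATACACTGTTGTCAATATG	CTAACAAAGAAATAAACCCGAG	ACGGATTTTTTTTTT-CAGTA	ACGGATTTTTTTTTTTCAGTA	Single nucleotide repeat	4727	4891	165	synthetic
cpINDEL2	AATTTCGTCGGCTCTAATGG	AGTTACATTTACGTACCATC	TATTATTATTA-------TTTTTTTTTTAAATAA	TATTATTATTATTTTTATTTTTTTTTTTAAATAA	Single nucleotide repeat	12533	12694	162	published
cpINDEL3	TAGAGTTCTTTTTGTATCAC	TATTCCGTAATTGATTGACA	TTTCTATTTATTTCTATTTAAA//ATTTTTTT-TTTTCA	TTTCTATTTA----------AA//ATTTTTTTTTTTTCA	Tandem/Single nucleotide repeat	13987	14168	182	published
cpINDEL4	GGATATGTGGTATAAAAATGGAG	CTTCACGTCCAGGATTACGTCC	CTTTTTTTTTTTTTAAAAAAAAAAAA----TGATC	C--------TTTTTAAAAAAAAAAAAAAAATGATC	Single nucleotide repeat	8331	8514	184	published
cpINDEL5	CACGTGTATGAATTCGTTAGG	ATTTTCTTTTGTTCAATTGAACAAAAG	TATTTTTTTTTTTTTTTTTTTATTATTATTTATTC	TATTTTTTTTTTTTTTTTTTT--TATTATTTATTC	Single nucleotide repeat	15341	15495	155	published
cpINDEL6	ATTGTAACAGAGGTGCAAGTG	GTATAAAGTGGAAGGGAAAGAGAG	TGGGTGGGGTGGGTACTTT//G-AAAAAAAAAAAC	TGGG-----TGGGTACTTT//GAAAAAAAAAAAAC	Single nucleotide repeat	32643	32810	168	published
cpINDEL7	GTATACTCATACTAGCTATAAC	TTCAAGAGACGGCTTATCTATC	AAATAAAGATTTCAACCTTTTTTTTTTTATTCTAA	AATAAAGATTTCAACC--TTTTTTTTTTATTCTAA	Single nucleotide repeat	34025	34159	135	published
cpINDEL8	GAATAGGTGGGTCAATTCCTTCC	CAAAATGGGATATACCTATGAG	CCCATTTTTTTT---ATTTACCCTATCTAATTGAA	TCCCATTTTTTTTTTATTTACCCTATCTAATTGAA	Single nucleotide repeat	45032	45178	147	published
cpINDEL9	GATCGAATCAAGATGTGTCAC	AATTGAAGTTCTATTTCTAAGTTC	GTTTAGAAATACTATAAATACTATATTAGATATTA	GTTTAGAAATACTATA----------------TTA	Tandem	71742	71910	169	published
cpINDEL10	TCCCTCTTCCATTTATCTGCATAC	GGACCTACCCATACTATGAAC	AAAGCAGATTGGTTTTT---------TTTATTTTA	AAAGCAGATTGGTTTTTCTTTTGTTTTTTATTTTA	No motif	86751	86955	205	published
cpINDEL11	GAATCGTAATGCTATGTACATTATC	TGAGATCCGATAGCTAGTATGG	TATACAGTATATTAT----GGTATTGTTACATTAC	TATACAGTATATTATGTATGGTATTGTTACATTAC	Tandem	30898	31076	179	published
cpINDEL12	GGGAAAAACGGGGATATTAGTG	TTCAAGAGACGGCTTATCTATC	AAATAAAGATTTCAACCTTTTTTTTTTTATTCTAAA	AATAAAGATTTCAACC--TTTTTTTTTTATTCTAAA	Single nucleotide repeat	33967	34159	193	published
cpINDEL13	TAGCATTGGAACTGCTATGTAGG	GGAACCACGGGAGGAATAGTG	TGGTTCAAGGCGT----AGCATTGGAACTGCTTGTA	TGGTTCAAGGCGTACCAAGCATTGGAACTGCTTGTA	No motif	47208	47398	191	published
cpINDEL14	CATAGATGAACTCCTATGAATG	CTTGAAATGAGACATGTACC	AGTCGATTAAATT--------TTGTCAAGCCATCCAT	AGTCGATTAAATTGGAATTAATTGTCAAGCCATCCAT	Tandem	53227	53381	155	published
cpINDEL15	TAGCTATAGAGTATCATATC	AAAATCCATTCTTGTCTTATC	CAACAAGATAAA-AAAAAAAAAAGAAAATCCTGCCTT	CAACAAGATAAAAAAAAAAAAAAGAAAATCCTGCCTT	Single nucleotide repeat	62375	62542	168	published
cpINDEL16	CTTACACTTACTTCGACTTAG	TTTCGTTGCAATCACAACCC	TAAAGTAAAGTTAAGTAAAGTAATAATAATATAGTAATATTA	T----TAAAGTTAAGTAAAGTAATAATAATATAGTA-----A	SSR	71159	71408	250	published
cpINDEL17	ATTCACAAGAACCGCGAATTC	CATTATAACAAGTCACACACTC	AACCGCGAATTCTT-----ATTAATACTTTTATACTTA	AACCGCGAATTCTTACTTTATTAATACTTTTATACTTA	No motif	78991	79205	215	published
cpINDEL18	ACTATTTATCTTAATATGGTTGT	TTAAGTTATTACTCACAACAAAG	TAATATAAATATAGAAAAGTAAAAA-----CCTATTG	TAATATAAATATAGAAAAGTAAAAATTTTTCCTATTG	Single nucleotide repeat	123167	123346	180	published
cpINDEL19	ATTCTTTCTTGTTCGTATTTTG	ACTTTGCTAAAAAATGACATAG	TTTGAAAATCCAATCCAAATAAAGTATTTTCTCTTGA	TTTGA------AATCCAAATAAAGTATTTTCTCTTGA	Tandem	130558	130730	173	published
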