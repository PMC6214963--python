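name	mature_5p_to_3p	length	LP	MFE	reads_BR	reads_BS	arm	location
Lc-miRn1-5p	GGAATGTTGTCTGGTGCGAGA	21	87	-52.9	2	2	5p	TR1186
Lc-miRn1-3p	TCGGACCAGGCTTCATTCCCC	21	87	-52.9	652	472	3p	TR1186
Lc-miRn5-5p	GGAATGTTGTCTGGCTCGAGG	21	154	-47.0	2	13	5p	TR16913
Lc-miRn5-3p	TCGGACCAGGCTTCATTCCCC	21	154	-47.0	433	314	3p	TR16913
Lc-miRn8-5p	AATGCGGTCTGGTTCGAGAGC	21	107	-46.6	10	18	5p	TR22538
Lc-miRn8-3p	TCTCGGACCAGGCTTCATTCT	21	107	-46.6	81	71	3p	TR22538
Lc-miRn10-5p	TGGAGAAGCAGGGCACGTGCTG	22	202	-56.6	40	28	5p	TR30054
Lc-miRn10-3p	TCATGTGCCCCTCTTCGCCATC	22	202	-56.6	1272	471	3p	TR30054
Lc-miRn13-5p	CCACAGCTTTCTTGAACTGCA	21	143	-63.7	100	109	5p	TR3658
Lc-miRn13-3p	GTTCAATAAAGCTGTGGGAAG	21	143	-63.7	26	16	3p	TR3658
Lc-miRn15-5p	TGGCATAGGCTACTTGGAAAC	21	133	-36.8	1508	932	5p	TR47641
Lc-miRn15-3p	TTCCAAGTCCACCCATGCCCGC	22	133	-36.8	1116	864	3p	TR47641
Lc-miRn25b-5p	TTCCACAGCTTTCTTGAACTT	21	166	-61.4	203	255	5p	TR6554
Lc-miRn25b-3p	GTTCAAGAAAGCTGTGGGAGA	21	166	-61.4	1	1	3p	TR6554
Lc-miRn37a-5p	TTCCACAGCTTTCTTGAACTT	21	143	-56.3	198	256	5p	TR9925
Lc-miRn37a-3p	CTCAAGAAAGCTGTGGGACATC	22	143	-56.3	274	229	3p	TR9925
Lc-miRn38-5p	GGAATGTTGGCTGGCTCGAGG	21	146	-44.5	4	7	5p	TR6110
Lc-miRn38-3p	TCGGACCAGGCTTCATTCCCC	21	146	-44.5	644	466	3p	TR6110
Lc-miRn39-5p	TTTTTCCACAGCTTTCTTGAACT	23	132	-32.7	513	1213	5p	Chr1
Lc-miRn39-3p	CTCAAGAAAGCTGTGGGAAATTA	23	132	-32.7	5426	363	3p	Chr1
Lc-miRn43-5p	CAGAGCTCCTTGAAGTCCAATA	22	236	-86.5	12	11	5p	Chr1
Lc-miRn43-3p	TTTGGATTGAAGGGAGCTCTA	21	236	-86.5	4061	3094	3p	Chr1
Lc-miRn54-5p	TGGAGAAGCAGGGCACGTGCAT	22	135	-66.6	1	4	5p	Chr3
Lc-miRn54-3p	TCATGTGCCCCTCTTCTCCATC	22	135	-66.6	261	111	3p	Chr3
Lc-miRn66-5p	TGGAGAAGCAGGGCACGTGCA	21	96	-40.2	1	3	5p	Chr7
Lc-miRn66-3p	CACGTGCTCCCCTTCTCCAAC	21	96	-40.2	35	13	3p	Chr7
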