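##gff-version 3
##sequence-region NC_012920.1 1 16569
NC_012920.1	conet_mito	D_loop	16024	16569	.	+	.	ID=feat1;Name=D-Loop;Note=control region, 3' part
NC_012920.1	conet_mito	D_loop	1	576	.	+	.	ID=feat2;Name=D-Loop;Note=control region, 5' part
NC_012920.1	conet_mito	tRNA	577	647	.	+	.	ID=feat3;Name=TRNF;Note=tRNA-Phe
NC_012920.1	conet_mito	rRNA	648	1601	.	+	.	ID=feat4;Name=RNR1;Note=12S ribosomal RNA
NC_012920.1	conet_mito	tRNA	1602	1670	.	+	.	ID=feat5;Name=TRNV;Note=tRNA-Val
NC_012920.1	conet_mito	rRNA	1671	3229	.	+	.	ID=feat6;Name=RNR2;Note=16S ribosomal RNA
NC_012920.1	conet_mito	tRNA	3230	3304	.	+	.	ID=feat7;Name=TRNL1;Note=tRNA-Leu(UUR)
NC_012920.1	conet_mito	CDS	3307	4262	.	+	.	ID=feat8;Name=ND1;Note=incomplete_stop
NC_012920.1	conet_mito	tRNA	4263	4331	.	+	.	ID=feat9;Name=TRNI;Note=tRNA-Ile
NC_012920.1	conet_mito	tRNA	4329	4400	.	-	.	ID=feat10;Name=TRNQ;Note=tRNA-Gln
NC_012920.1	conet_mito	tRNA	4402	4469	.	+	.	ID=feat11;Name=TRNM;Note=tRNA-Met
NC_012920.1	conet_mito	CDS	4470	5511	.	+	.	ID=feat12;Name=ND2;Note=incomplete_stop
NC_012920.1	conet_mito	tRNA	5512	5579	.	+	.	ID=feat13;Name=TRNW;Note=tRNA-Trp
NC_012920.1	conet_mito	tRNA	5587	5655	.	-	.	ID=feat14;Name=TRNA;Note=tRNA-Ala
NC_012920.1	conet_mito	tRNA	5657	5729	.	-	.	ID=feat15;Name=TRNN;Note=tRNA-Asn
NC_012920.1	conet_mito	rep_origin	5721	5798	.	+	.	ID=feat16;Name=ORIL;Note=light-strand replication origin
NC_012920.1	conet_mito	tRNA	5761	5826	.	-	.	ID=feat17;Name=TRNC;Note=tRNA-Cys
NC_012920.1	conet_mito	tRNA	5826	5891	.	-	.	ID=feat18;Name=TRNY;Note=tRNA-Tyr
NC_012920.1	conet_mito	CDS	5904	7445	.	+	.	ID=feat19;Name=COX1
NC_012920.1	conet_mito	tRNA	7446	7514	.	-	.	ID=feat20;Name=TRNS1;Note=tRNA-Ser(UCN)
NC_012920.1	conet_mito	tRNA	7518	7585	.	+	.	ID=feat21;Name=TRND;Note=tRNA-Asp
NC_012920.1	conet_mito	CDS	7586	8269	.	+	.	ID=feat22;Name=COX2
NC_012920.1	conet_mito	tRNA	8295	8364	.	+	.	ID=feat23;Name=TRNK;Note=tRNA-Lys
NC_012920.1	conet_mito	CDS	8366	8572	.	+	.	ID=feat24;Name=ATP8
NC_012920.1	conet_mito	CDS	8527	9207	.	+	.	ID=feat25;Name=ATP6
NC_012920.1	conet_mito	CDS	9207	9990	.	+	.	ID=feat26;Name=COX3;Note=incomplete_stop
NC_012920.1	conet_mito	tRNA	9991	10058	.	+	.	ID=feat27;Name=TRNG;Note=tRNA-Gly
NC_012920.1	conet_mito	CDS	10059	10404	.	+	.	ID=feat28;Name=ND3;Note=incomplete_stop
NC_012920.1	conet_mito	tRNA	10405	10469	.	+	.	ID=feat29;Name=TRNR;Note=tRNA-Arg
NC_012920.1	conet_mito	CDS	10470	10766	.	+	.	ID=feat30;Name=ND4L
NC_012920.1	conet_mito	CDS	10760	12137	.	+	.	ID=feat31;Name=ND4;Note=incomplete_stop
NC_012920.1	conet_mito	tRNA	12138	12206	.	+	.	ID=feat32;Name=TRNH;Note=tRNA-His
NC_012920.1	conet_mito	tRNA	12207	12265	.	+	.	ID=feat33;Name=TRNS2;Note=tRNA-Ser(AGY)
NC_012920.1	conet_mito	tRNA	12266	12336	.	+	.	ID=feat34;Name=TRNL2;Note=tRNA-Leu(CUN)
NC_012920.1	conet_mito	CDS	12337	14148	.	+	.	ID=feat35;Name=ND5
NC_012920.1	conet_mito	CDS	14149	14673	.	-	.	ID=feat36;Name=ND6
NC_012920.1	conet_mito	tRNA	14674	14742	.	-	.	ID=feat37;Name=TRNE;Note=tRNA-Glu
NC_012920.1	conet_mito	CDS	14747	15887	.	+	.	ID=feat38;Name=CYTB;Note=incomplete_stop
NC_012920.1	conet_mito	tRNA	15888	15953	.	+	.	ID=feat39;Name=TRNT;Note=tRNA-Thr
NC_012920.1	conet_mito	tRNA	15956	16023	.	-	.	ID=feat40;Name=TRNP;Note=tRNA-Pro
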