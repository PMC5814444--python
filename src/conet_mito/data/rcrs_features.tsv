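# Human mtDNA reference feature map (rCRS, GenBank NC_012920.1), reference length 16569.
# Columns: name  start  end  strand  kind  notes
# The control region spans the origin and is split into two records.
# CDS records whose length is not divisible by 3 end in polyadenylation-completed
# stop codons and carry the incomplete_stop note.
D-Loop	16024	16569	+	D-Loop	control region, 3' part
D-Loop	1	576	+	D-Loop	control region, 5' part
TRNF	577	647	+	tRNA	tRNA-Phe
RNR1	648	1601	+	rRNA	12S ribosomal RNA
TRNV	1602	1670	+	tRNA	tRNA-Val
RNR2	1671	3229	+	rRNA	16S ribosomal RNA
TRNL1	3230	3304	+	tRNA	tRNA-Leu(UUR)
ND1	3307	4262	+	CDS	incomplete_stop
TRNI	4263	4331	+	tRNA	tRNA-Ile
TRNQ	4329	4400	-	tRNA	tRNA-Gln
TRNM	4402	4469	+	tRNA	tRNA-Met
ND2	4470	5511	+	CDS	incomplete_stop
TRNW	5512	5579	+	tRNA	tRNA-Trp
TRNA	5587	5655	-	tRNA	tRNA-Ala
TRNN	5657	5729	-	tRNA	tRNA-Asn
ORIL	5721	5798	+	ORIL	light-strand replication origin
TRNC	5761	5826	-	tRNA	tRNA-Cys
TRNY	5826	5891	-	tRNA	tRNA-Tyr
COX1	5904	7445	+	CDS	.
TRNS1	7446	7514	-	tRNA	tRNA-Ser(UCN)
TRND	7518	7585	+	tRNA	tRNA-Asp
COX2	7586	8269	+	CDS	.
TRNK	8295	8364	+	tRNA	tRNA-Lys
ATP8	8366	8572	+	CDS	.
ATP6	8527	9207	+	CDS	.
COX3	9207	9990	+	CDS	incomplete_stop
TRNG	9991	10058	+	tRNA	tRNA-Gly
ND3	10059	10404	+	CDS	incomplete_stop
TRNR	10405	10469	+	tRNA	tRNA-Arg
ND4L	10470	10766	+	CDS	.
ND4	10760	12137	+	CDS	incomplete_stop
TRNH	12138	12206	+	tRNA	tRNA-His
TRNS2	12207	12265	+	tRNA	tRNA-Ser(AGY)
TRNL2	12266	12336	+	tRNA	tRNA-Leu(CUN)
ND5	12337	14148	+	CDS	.
ND6	14149	14673	-	CDS	.
TRNE	14674	14742	-	tRNA	tRNA-Glu
CYTB	14747	15887	+	CDS	incomplete_stop
TRNT	15888	15953	+	tRNA	tRNA-Thr
TRNP	15956	16023	-	tRNA	tRNA-Pro
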