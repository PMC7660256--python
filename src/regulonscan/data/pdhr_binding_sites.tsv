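# PdhR binding sites identified by genomic SELEX screening on the E. coli K-12
# genome (35 sites above the intensity-500 cutoff), transcribed from the
# published binding-site table.
#
# Column-order note: the published table prints the intensity columns as
# "Intensity (PdhR+pyruvate)" followed by "Intensity (PdhR alone)", but the
# accompanying text applies the 500 cutoff to the screening performed in the
# ABSENCE of effector and states that intensities decreased in the presence of
# pyruvate; the first printed column is consistently the larger of the two.
# The only reading consistent with both is that the first printed column is
# the no-effector screening, so it is stored here as intensity_no_effector and
# the second printed column as intensity_effector.
#
# left_strand / right_strand transcribe the printed transcription-direction
# arrows ('>' = +, '<' = -). For intragenic (type-D) rows the host gene's
# strand is not printed; it is stored as '+' by convention and is never used.
# Missing printed values (en dash in the original) are stored as ASCII '-'.
#
# The acpP row (peak 1150668) prints the site sequence "AcaTGGTctgACCgctt"
# with conservation "8/14" and motif position 1150625. That printed entry is
# internally inconsistent: the final two bases (tt) match the box consensus
# (..TT) case-insensitively, so any consistent count of matched informative
# positions gives 10/14, and the printed lowercase casing contradicts the
# letters themselves. Because the printed sequence and score cannot both be
# right and neither can be reconstructed, the motif columns of that row are
# stored as absent; the printed values are preserved in this comment.
peak_position	intensity_no_effector	intensity_effector	site_type	left_gene	left_strand	host_gene	right_gene	right_strand	regulated	left_operon	left_function	right_operon	right_function	site_sequence	conservation	motif_position	database
121966	9889	9234	A	aroP	-	-	pdhR	+	aroP,pdhR	aroP	aromatic amino acid:H+ symporter	pdhR-aceEF-lpd	regulator of pyruvate dehydrogenase	AATTGGTaagACCAATT	14/14	122052	pdhR
243432	655	290	A	fadE	-	-	lpcA	+	fadE,lpcA	fadE	acyl-CoA dehydrogenase	lpcA	D-sedoheptulose 7-phosphate isomerase	tccTGGTcatAgCAccT	8/14	243459	-
578844	556	239	A	ybcV	-	-	ybcW	+	ybcV,ybcW	ybcV	DLP12; DUF1398 domain-containing protein	ybcW	DLP12 prophage; uncharacterized protein	AtcTGGTctgACCtcTT	10/14	578887	-
1753972	555	352	A	fumD	-	-	pykF	+	fumD,pykF	fumD	fumarase D	pykF	pyruvate kinase I	AgcTGGTcagACCttTa	9/14	1753987	-
1785030	679	251	A	ppsA	-	-	ppsR	+	ppsA,ppsR	ppsA	phosphoenolpyruvate synthetase	ppsR	PEP synthetase regulatory protein	AgTTGGTtatACCAAag	11/14	1785098	-
2714448	6197	3323	A	grcA	-	-	ung	+	grcA,ung	grcA	stress-induced alternate pyruvate formate-lyase	ung	uracil-DNA glycosylase	AATTGGTaaaACCAtTg	12/14	2714529	grcA
3126270	795	488	A	glcD	-	-	glcC	+	glcD,glcC	glcDEFGBA	glycolate dehydrogenase	glcC	DNA-binding transcriptional dual regulator	AATTGGTcctACCtgTg	11/14	3126271	glcD
450964	2995	2315	B	cyoA	-	-	ampG	-	cyoA	cyoABCDE	cytochrome bo3 ubiquinol oxidase subunit 2	-	-	AATTGGTataACCAATg	13/14	451054	cyoA
770852	509	390	B	mngB	+	-	cydA	+	cydA	-	-	cydAB	cytochrome bd-I ubiquinol oxidase	tAaaGaTatgACCAAgT	9/14	770832	-
1150668	697	180	B	fabG	+	-	acpP	+	acpP	-	-	acpP-fabF	acyl carrier protein	-	-	-	-
1165072	3993	4550	B	ycfP	+	-	ndh	+	ndh	-	-	ndh	NADH:quinone oxidoreductase II	ttTTGGTatgACCAATg	11/14	1165180	ndh
1831272	573	99	B	xthA	+	-	ydjX	+	ydjX	-	-	ydjXYZABCD	DedA family protein	-	-	-	-
2000362	584	87	B	fliA	-	-	fliC	-	fliA	fliAZ	RNA polymerase sigma 28 (sigma F) factor	-	-	AAaTGGTaaaACCAcgg	10/14	2000414	-
2458466	1266	1122	B	fadI	-	-	yfcZ	-	fadI	fadIJ	3-ketoacyl-CoA thiolase	-	-	cAgcGGTaaaACCtgac	7/14	2458479	-
2839166	3469	383	B	ascF	+	-	ascB	+	ascB	-	-	ascB	6-phospho-beta-glucosidase	cAaaGGTctgACCAcTg	9/14	2839100	-
3775254	632	943	B	yibL	+	-	lldP	+	lldP	-	-	lldPDR	lactate/glycolate:H+ symporter	AATTGGccctACCAATT	13/14	3775215	-
92666	1113	114	D	ftsL	+	ftsI	murE	+	-	-	-	ftsLI-murEF-mraY-murD-ftsW-murGC-ddIB-ftsQAZ-lpxC	UDP-N-acetylmuramoyl-L-alanyl-D-glutamate--2,6-diaminopimelate ligase	tAaTGGTaacACCAtTa	10/14	92682	-
173132	557	74	D	fhuD	+	fhuB	hemL	-	-	-	-	-	-	-	-	-	-
435948	755	584	D	thiL	+	pgpA	yajO	-	-	-	-	-	-	AAagGaTatgACCAtTT	10/14	435814	-
480770	541	16	D	tomB	-	acrB	acrA	-	-	tomB-hha	Hha toxicity modulator	-	-	AAcgGaatcgACCAgcT	8/14	480940	tomB
856236	1265	1063	D	ldtB	-	ybiT	ybiU	-	-	ldtB	L,D-transpeptidase	-	-	AAaTGaTctgACCgtgT	9/14	856381	-
999430	1083	103	D	elfD	+	elfC	elfG	+	-	-	-	elfDCG-ycbUVF	putative fimbrial-like adhesin protein	AAaTGGTtacACCAtTT	12/14	999352	-
1412370	795	21	D	ralR	-	recT	recE	-	-	recET-ralR-rcbA-xisR-intR	Rac prophage; endodeoxyribonuclease toxin	-	-	-	-	-	-
1635148	820	407	D	ynfO	+	ydfO	gnsB	-	-	-	-	-	-	AAcaGGTcagACCAgaT	10/14	1635002	-
1676572	978	128	D	pntA	-	ydgH	ydgI	+	-	pntAB	pyridine nucleotide transhydrogenase	ydgI-folM	putative arginine:ornithine antiporter	-	-	-	-
1738666	1142	321	D	ydhB	-	ydhC	cfa	+	-	ydhB	LysR family DNA-binding transcriptional regulator	cfa	cyclopropane fatty acyl phospholipid synthase	ggaTGGTctgACCttTa	8/14	1738515	-
2037932	629	65	D	yedX	+	msrP	msrQ	+	-	-	-	msrPQ	periplasmic protein-L-methionine sulfoxide reductase	AAgTGGcaaaACCAtTg	10/14	2037865	-
2075930	976	1124	D	yeeU	+	yeeV	yeeW	+	-	-	-	yeeRST-cbeA-cbtA-yeeW	CP4-44 prophage; uncharacterized protein	-	-	-	-
2131938	2066	174	D	wcaA	-	wzc	wzb	-	-	wcaAB	colanic acid biosynthesis glycosyl transferase	-	-	AATTGGTaaaACCttTg	11/14	2132058	-
2317232	1633	968	D	rcsB	+	rcsC	atoS	+	-	-	-	atoSC	sensory histidine kinase	tcagGGTatgACCAtTT	9/14	2317144	-
2517448	851	74	D	yfeD	+	gltX	valU	+	-	-	-	valU	tRNA-Val(UAC)	tgcgGGTcttACCAATT	10/14	2517346	-
3673834	735	230	D	yhjD	+	yhjE	yhjG	-	-	-	-	-	-	-	-	-	-
3997946	740	12	D	yigB	+	uvrD	yigE	-	-	-	-	-	-	-	-	-	-
4357756	552	484	D	cadA	-	cadB	cadC	-	-	cadA	lysine decarboxylase 1	-	-	tAgTGGTtaaACggcTT	9/14	4357618	-
4616836	509	216	D	deoC	+	deoA	deoB	+	-	-	-	deoBD	phosphopentomutase	cgTTaGccacgCCAAca	7/14	4616931	-
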