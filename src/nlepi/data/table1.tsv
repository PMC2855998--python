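sample_id	group	age	distance_from_tumour	er	pr	her2	stage	bc_history	prior_study_flag
319H	HN	34	<2cm	-	-	-	IIIA		0
316H	HN	39	<2cm	+	-	-	IIA		1
379H	HN	43	<2cm	+	+	+	I		0
251H	HN	45	<2cm	+	+	-	0		1
289H	HN	47	<2cm	-	-	-	IIA		0
364H	HN	47	>2cm	-	-	+	IIIA		0
342H	HN	48	<2cm	-	-	-	IIA		0
304BH	HN	49	<2cm	+	+	+	I		1
273H	HN	49	<2cm	-	-	+	III		0
380H	HN	53	<2cm	+	+	+	IIA		0
446BH	HN	54	>2cm	+	+	-	IIIA		0
237H	HN	55	?	+	-	-	I		1
322H	HN	58	<2cm	-	-	-	I		0
272H	HN	58	>2cm	-	-	+	IIIC		0
388AH	HN	58	<2cm	+	-	-	I		0
232H	HN	59	>2cm	+	+	na	0		0
226H	HN	61	<2cm	-	-	na	IIIA		1
333H	HN	76	>2cm	-	-	+	IIB		0
360R	RM	36							1
352R	RM	41							1
347R	RM	43							1
278R	RM	44							1
373R	RM	44							0
350R	RM	47							1
309R	RM	49							1
357R	RM	49							1
368R	RM	49							1
288R	RM	52							1
402R	RM	55							0
383R	RM	55							0
406R	RM	56							0
396R	RM	57							0
361R	RM	57							1
419R	RM	57							0
310R	RM	60							1
305R	RM	75							0
395P	PM	35						+	0
276P	PM	36						-	0
451P	PM	43						+	0
242P	PM	46						+	0
446AP	PM	54						+	0
249P	PM	57						-	0
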