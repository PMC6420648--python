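code	family	variant	params	kinds
cpr	correlation	pearson	-	ts,ss
csp	correlation	spearman	-	ts,ss
ckd	correlation	kendall	-	ts,ss
mfo	information	mi	estimator=ml;discretization=equal_freq	ts,ss
mfm	information	mi	estimator=mm;discretization=equal_freq	ts,ss
mfs	information	mi	estimator=shrink;discretization=equal_freq	ts,ss
mwo	information	mi	estimator=ml;discretization=equal_width	ts,ss
dmn	distance	s1	-	ts,ss
dec	distance	s2	-	ts,ss
d10	distance	s10	-	ts,ss
ws1	dtw	symmetric1	-	ts
ws2	dtw	symmetric2	-	ts
was	dtw	asymmetric	-	ts
sqd	symbolic	qd	-	ts
sss	symbolic	seq	-	ts
smf	symbolic	mi	symbolization=equal_freq	ts
smw	symbolic	mi	symbolization=equal_width	ts
saf	symbolic	combined	symbolization=equal_freq	ts
saw	symbolic	combined	symbolization=equal_width	ts
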