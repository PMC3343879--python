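# SYNTHETIC positional residue table (IMGT-style) for the alleles used in tests.
# 1-based mature-protein coordinates in the header row define the numbering.
# HLA-B position 80 (Bw4-80I/80T vs Bw6) and position 116 (116Y carriers),
# HLA-C position 80 (C1/C2 N/K) follow published epitope definitions; all
# other residues are synthetic placeholders with realistic level structure.
allele	9	24	62	67	70	80	97	99	107	116	145	156
A*01:01	F	A	Q	M	H	I	R	Y	W	D	R	L
A*02:01	F	A	G	V	H	T	M	Y	G	Y	R	W
A*03:01	F	A	Q	M	Q	T	I	F	G	D	R	L
B*57:01	Y	T	G	C	S	I	V	Y	G	S	R	L
B*13:02	H	T	G	S	N	I	V	Y	G	F	R	L
B*38:01	Y	T	R	C	N	I	T	Y	G	F	R	L
B*51:01	Y	A	G	F	Q	I	T	Y	G	Y	R	L
B*27:05	H	A	R	C	K	T	N	Y	W	D	R	L
B*44:02	D	A	R	S	N	T	R	Y	G	D	R	L
B*44:03	D	A	R	S	N	T	R	Y	G	D	L	L
B*44:05	D	A	R	S	N	T	R	Y	G	Y	R	L
B*37:01	H	A	R	S	N	T	T	Y	G	S	R	R
B*07:02	H	A	R	Y	Q	N	S	Y	G	Y	R	L
B*08:01	D	A	R	F	N	N	N	Y	G	Y	R	L
B*14:02	H	A	R	F	Q	N	R	Y	G	F	R	L
B*18:01	H	A	R	F	N	N	T	Y	G	D	R	L
B*35:01	Y	A	R	F	Q	N	S	Y	G	S	R	L
B*35:02	Y	A	R	F	Q	N	S	Y	G	Y	R	W
B*35:03	Y	A	R	F	Q	N	S	F	G	F	R	L
B*39:01	H	A	R	C	N	N	N	Y	G	S	R	L
B*40:01	H	A	R	S	N	N	R	Y	G	Y	R	L
B*40:02	H	A	R	S	N	N	R	Y	G	Y	L	L
B*55:01	H	A	R	Y	Q	N	S	Y	G	F	R	L
C*01:02	F	A	G	Y	Q	N	W	Y	G	F	R	R
C*02:02	Y	A	G	Y	Q	K	W	Y	G	F	R	L
C*03:04	F	A	G	Y	Q	N	W	Y	G	F	R	L
C*04:01	Y	A	G	Y	Q	K	W	F	G	F	R	L
C*05:01	Y	A	G	Y	Q	K	R	Y	G	F	R	R
C*06:02	D	S	G	Y	Q	K	W	Y	G	F	R	W
C*07:01	Y	A	G	Y	Q	N	R	Y	G	S	R	R
C*07:02	Y	A	G	Y	Q	N	R	Y	G	S	L	R
C*12:03	F	A	G	Y	Q	N	W	Y	G	F	R	W
C*15:02	Y	A	G	Y	Q	K	W	Y	G	F	R	L
C*16:01	F	A	G	Y	Q	N	W	Y	G	F	R	L
DQA1*01:01	F	A	Q	M	H	T	M	Y	G	D	R	L
DQA1*01:02	F	A	Q	M	H	T	M	Y	G	D	R	W
DQA1*02:01	Y	S	G	C	K	I	V	F	W	Y	L	R
DQA1*03:01	F	A	R	S	N	N	R	Y	G	F	R	L
DQA1*05:01	F	A	R	S	N	N	R	Y	G	F	R	W
DQB1*02:02	Y	A	G	C	K	I	V	Y	G	Y	R	L
DQB1*03:02	F	A	R	S	N	N	R	Y	G	F	R	L
DQB1*03:03	Y	S	G	C	K	I	V	F	W	Y	L	R
DQB1*05:01	F	A	Q	M	H	T	M	Y	G	D	R	L
DQB1*05:02	F	A	Q	M	H	T	M	Y	G	D	R	W
DQB1*06:04	F	A	Q	M	Q	T	I	F	G	D	R	L
DRB1*01:01	F	A	Q	M	H	T	M	Y	G	D	R	L
DRB1*04:04	F	A	R	S	N	N	R	Y	G	F	R	L
DRB1*07:01	Y	S	G	C	K	I	V	F	W	Y	L	R
DRB1*13:02	F	A	Q	M	Q	T	I	F	G	D	R	L
DRB1*15:01	F	A	Q	M	H	I	R	Y	W	D	M	L
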