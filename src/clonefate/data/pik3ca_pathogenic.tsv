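gene	aa_change	class	source
PIK3CA	R38H	Path/GoF	CKB
PIK3CA	R88Q	Path/GoF	ClinVar
PIK3CA	R93W	Path/GoF	CKB
PIK3CA	K111E	Path/GoF	ClinVar
PIK3CA	K111N	Path/GoF	CKB
PIK3CA	G118D	Path/GoF	ClinVar
PIK3CA	V344M	Path/GoF	CKB
PIK3CA	N345K	Path/GoF	ClinVar
PIK3CA	C420R	Path/GoF	ClinVar
PIK3CA	E453K	Path/GoF	CKB
PIK3CA	P471L	Path/GoF	CKB
PIK3CA	E542K	Path/GoF	ClinVar
PIK3CA	E545K	Path/GoF	ClinVar
PIK3CA	E545A	Path/GoF	ClinVar
PIK3CA	E545G	Path/GoF	ClinVar
PIK3CA	E545Q	Path/GoF	CKB
PIK3CA	Q546K	Path/GoF	ClinVar
PIK3CA	Q546R	Path/GoF	ClinVar
PIK3CA	Q546P	Path/GoF	CKB
PIK3CA	E726K	Path/GoF	ClinVar
PIK3CA	E970K	Path/GoF	CKB
PIK3CA	M1043I	Path/GoF	ClinVar
PIK3CA	M1043V	Path/GoF	CKB
PIK3CA	N1044K	Path/GoF	CKB
PIK3CA	H1047R	Path/GoF	ClinVar
PIK3CA	H1047L	Path/GoF	ClinVar
PIK3CA	H1047Y	Path/GoF	ClinVar
PIK3CA	G1049R	Path/GoF	ClinVar
PIK3CA	G1049S	Path/GoF	CKB
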