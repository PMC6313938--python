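# S8 (subtilisin) domain proteins of the C. reinhardtii genome:
# protein_id, length, signal-peptide span (or "no"), TM-helix span (or "no").
protein_id	length	signal	tm_helix
Cre02.g076950	1355	1-22	no
Cre04.g213400	539	1-23	no
Cre07.g329500	945	1-29	no
Cre10.g459450	866	1-30	no
Cre05.g242100	1264	1-26	no
Cre05.g242750	1301	1-23	no
Cre19.g750447	1141	1-26	no
Cre14.g628800	1787	1-47	1719-1741
Cre01.g049950	1117	no	37-59
Cre03.g145827	1512	no	45-67
Cre16.g685250	1532	no	55-77
Cre17.g708400	1794	no	451-473
Cre17.g735450	1674	no	138-160
Cre03.g190250	1229	no	1149-1171
Cre13.g585800	809	no	no
Cre16.g675350	1492	no	no
Cre17.g713600	1982	no	no
Cre03.g170300	1374	no	no
Cre05.g242700	777	no	no
Cre05.g242856	1419	no	no
Cre09.g406700	1890	no	no
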