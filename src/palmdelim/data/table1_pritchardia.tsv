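# Transcription of the published conformance table for Hawaiian Pritchardia
# (three species-delimitation criteria per putative lineage).
# gsc_satisfied encodes the table's bold genotypic-cluster cells: lineages that
# meet both the necessary (>0.8 mean membership) and sufficiency (exclusivity)
# conditions; '-' marks lineages not assessed for that criterion.
lineage	monophyletic	genotypic_cluster	gsc_satisfied	diagnosable
affinis	58%	12; 0.91	yes	No
arecina	No	19; 0.71	no	Yes
aylmer-robinsonii	No	18; 0.91	yes	Yes
bakeri Kuliouou	No	13; 0.67	no	No
bakeri Pupukea	62%	17; 0.51	no	Yes
beccariana	No	14; 0.90	no	No
elliptica Kunoa	No	4; 0.48	no	No
elliptica Lanai City	No	-	-	No
flynii	No	11; 0.40	no	No
forbesiana	No	10; 0.83	no	Yes
glabrata	76%	20; 0.58	no	Yes
gordonii	-	-	-	Yes
hardyi	No	7; 0.86	yes	Yes
hillebrandii	No	14; 0.59	no	Yes
kaalae	63%	11; 0.31	no	Yes
kahukuensis	No	21; 0.52	no	No
lanaiensis	No	8; 0.46	no	No
lanigera	No	9; 0.55	no	No
limahuliensis	No	4; 0.78	no	No
lowreyana	No	15; 0.89	no	Yes
maideniana	No	-	-	Yes
martii Ewa	No	21; 0.44	no	No
martii Waiawa	No	19; 0.54	no	Yes
martii Waianae	No	11; 0.31	no	No
minor	No	4; 0.62	no	No
munroi	No	16; 0.83	yes	Yes
napaliensis	No	4; 0.52	no	No
perlmanii	72%	10; 0.57	no	No
remota	58%	11; 0.51	no	Yes
schattaueri	No	2; 0.91	yes	Yes
viscosa	No	16; 0.40	no	Yes
waialealeana	No	9; 0.50	no	Yes
woodii	-	-	-	Yes
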