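subject_id	side	landmark	x	y	z	frame
S01	right	AC	0.0	0.0	0.0	acpc
S01	right	PC	0.0	-23.950074089013746	0.0	acpc
S01	right	hippocampal_sulcus	33.21536071218443	-7.0164884952531255	-13.023698207157135	acpc
S01	right	innominate_sulcus	47.07855143266841	-7.0164884952531255	-17.491983046969626	acpc
S01	right	limen_insulae	32.14695607242642	6.879397974862829	-13.222208064571051	acpc
S01	right	midsagittal	0.0	4.445412909364219	43.63814091119212	acpc
S01	right	sphenoid_inner	12.467509342252045	9.140707537116763	-15.631249215917501	acpc
S01	right	sphenoid_outer	39.76816931377471	-18.02057936041343	-14.752798914610228	acpc
S01	left	AC	0.0	0.0	0.0	acpc
S01	left	PC	0.0	-23.487757270928462	0.0	acpc
S01	left	hippocampal_sulcus	-36.638625215118125	-6.485537206883631	-17.81621323608841	acpc
S01	left	innominate_sulcus	-47.80645746222993	-6.485537206883631	-21.21637624726951	acpc
S01	left	limen_insulae	-34.22254133867403	3.8454705179311977	-16.42832782216311	acpc
S01	left	midsagittal	0.0	2.558681815256367	46.23195884515099	acpc
S01	left	sphenoid_inner	-12.365444064364079	10.412732611595988	-15.569178996992118	acpc
S01	left	sphenoid_outer	-42.23724268596661	-21.836142728642084	-15.975594013376734	acpc
S02	right	AC	0.0	0.0	0.0	acpc
S02	right	PC	0.0	-23.529627345707205	0.0	acpc
S02	right	hippocampal_sulcus	35.6974283583128	-5.967370233270998	-14.035039802372744	acpc
S02	right	innominate_sulcus	46.535943259968654	-5.967370233270998	-16.63476440979807	acpc
S02	right	limen_insulae	33.116685809140726	6.218688596729013	-13.12857122205181	acpc
S02	right	midsagittal	0.0	3.0833664552699744	44.449715497546634	acpc
S02	right	sphenoid_inner	12.067579069488891	10.289119398689984	-15.36871177416146	acpc
S02	right	sphenoid_outer	39.36662810550844	-23.759771882105902	-15.688382990518761	acpc
S02	left	AC	0.0	0.0	0.0	acpc
S02	left	PC	0.0	-23.537648207335433	0.0	acpc
S02	left	hippocampal_sulcus	-35.79923299179083	-9.706738556702668	-14.38226946972784	acpc
S02	left	innominate_sulcus	-49.19064963067797	-9.706738556702668	-18.677266041975916	acpc
S02	left	limen_insulae	-34.4949413112344	3.1341688843067566	-15.031721645408519	acpc
S02	left	midsagittal	0.0	7.573927643771461	44.61739135023677	acpc
S02	left	sphenoid_inner	-12.162753065105006	10.586222331359279	-15.288773420207145	acpc
S02	left	sphenoid_outer	-38.051157320629656	-20.470256334126717	-15.637498492455583	acpc
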