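genus	guilds	kegg_modules	ko_ids
Thermodesulfovibrio	sulfate_reduction	M00596	K00958;K00394;K00395;K11180;K11181
Desulfotomaculum	sulfate_reduction	M00596	K00958;K00394;K00395;K11180;K11181
Desulfocucumis	sulfate_reduction	M00596	K00958;K00394;K00395;K11180;K11181
Desulfofarcimen	sulfate_reduction	M00596	K00958;K00394;K00395;K11180;K11181
Desulfocurvus	sulfate_reduction	M00596	K00958;K00394;K00395;K11180;K11181
Desulfolutivibrio	sulfate_reduction	M00596	K00958;K00394;K00395;K11180;K11181
Methanothermobacter	methanogenesis	M00567	K00399;K00401;K00402;K00319;K00320
Methanobacterium	methanogenesis	M00567	K00399;K00401;K00402;K00319;K00320
Acetobacterium	wood_ljungdahl	M00377	K00198;K14138;K01938;K01491;K15023
Moorella	wood_ljungdahl	M00377	K00198;K14138;K01938;K01491;K15023
Rectinema	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
Caldicoprobacter	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
Pelotomaculum	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
Tepidanaerobacter	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
Anaerovorax	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
Macellibacteroides	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
Marcellibacteroides	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
Proteiniphilum	fermentation	FERM	K00016;K00656;K00925;K13788;K00001
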