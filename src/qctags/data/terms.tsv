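#qctags core vocabulary v1.0.0	GENEPIO-backed QC contextual-data tag terms
label	curie	category	synonyms	provenance
quality control method name	GENEPIO:0100557	field		core
quality control method version	GENEPIO:0100558	field		core
quality control determination	GENEPIO:0100559	field		core
quality control issues	GENEPIO:0100560	field		core
quality control details	GENEPIO:0100561	field		core
experimental specimen role type		field		core
experimental specimen details		field		core
no quality control issues identified	GENEPIO:0100562	determination	no quality control issues	core
sequence passed quality control	GENEPIO:0100563	determination		core
sequence failed quality control	GENEPIO:0100564	determination		core
minor quality control issues identified	GENEPIO:0100565	determination	minor quality control issues	core
sequence flagged for potential quality control issues	GENEPIO:0100566	determination	potential quality control issues	core
quality control not performed	GENEPIO:0100567	determination	not performed	core
low quality sequence	GENEPIO:0100568	issue		core
sequence contaminated	GENEPIO:0100569	issue	sequenced contaminated	core
low average genome coverage	GENEPIO:0100570	issue		core
low percent genome captured	GENEPIO:0100571	issue		core
read lengths shorter than expected	GENEPIO:0100572	issue		core
sequence amplification artefacts	GENEPIO:0100573	issue	sequence amplification artifacts	core
low signal to noise ratio	GENEPIO:0100574	issue		core
low coverage of characteristic mutations	GENEPIO:0100575	issue		core
excess frameshift mutations detected	GENEPIO:0100751	issue		core
taxonomic designation inconsistent across methods	GENEPIO:0101038	issue		core
Not Applicable	GENEPIO:0001619	misc		core
synthetic lab construct	GENEPIO:0101039	misc		core
FastANI		method		core
FastQC		method		core
Kraken2		method		core
Mash		method		core
Nextclade		method		core
ncov-tools		method		core
PHoeNIx		method		core
Quast		method		core
samtools depth		method		core
Samtools		method		core
VADR		method		core
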