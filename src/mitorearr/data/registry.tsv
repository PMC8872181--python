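label	iqm_or_qim	hotspot	description
typical	IQM	tRNA-Pro,CR,tRNA-Phe	typical vertebrate mitochondrial gene order
V	QIM	CR,tRNA-Pro,tRNA-Phe,CR	duplicated control region, tRNA-Pro upstream of tRNA-Phe
IX	QIM	CR,tRNA-Phe,tRNA-Pro,CR,tRNA-Phe,CR	three control regions with an extra tRNA-Phe copy
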