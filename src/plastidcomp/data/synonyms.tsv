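# alias	canonical
ycf13	mat1
rpl3	ycf65
psbZ	psbZ
ycf9	psbZ
rrn16s	rrn16
rrn23s	rrn23
16s	rrn16
23s	rrn23
16s rrna	rrn16
23s rrna	rrn23
16s ribosomal rna	rrn16
23s ribosomal rna	rrn23
rrnl	rrn23
rrns	rrn16
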