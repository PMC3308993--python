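# Published genome records (drop-in)

Place the following GenBank/EMBL flat files here to enable the
accession-based acceptance targets (t5-t12) and the corresponding
acceptance test:

* `HE605038.gb` — Eutreptiella gymnastica plastid genome
* `X70810.gb` — Euglena gracilis plastid genome
* `pyramimonas_parkeae.gb` — Pyramimonas parkeae plastid genome

Example fetch (requires network / NCBI EDirect):

    efetch -db nuccore -id HE605038 -format gb > HE605038.gb
    efetch -db nuccore -id X70810   -format gb > X70810.gb
    efetch -db nuccore -id NC_012097 -format gb > pyramimonas_parkeae.gb

Nothing in this directory is required for the rest of the test suite.
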