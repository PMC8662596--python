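# data/

Place a GenBank flatfile copy of record **MW553037** here as `MW553037.gb`
to enable the accession-backed acceptance targets (t1-t4):

    efetch -db nuccore -id MW553037 -format gbwithparts > data/MW553037.gb

`scripts/acceptance.py` and
`tests/test_acceptance.py::TestCriterion8AccessionBackedTargets` read it from
this path. Nothing else in the package requires downloads.
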