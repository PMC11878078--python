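{
 "table1_cohort.tsv": "daf03e022c57cbd428d429409a3c6b941de2cad167245d520d76fe0cdd5d9223",
 "table2_catalog.tsv": "a67cf9f6ec818ca7d6d8cf9164039c0dd0667919486e97cd83e6b90b21363e33"
}
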