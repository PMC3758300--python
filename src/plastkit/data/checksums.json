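{
 "table2.tsv": "6b7a255af6a22da816d2043f6f530ac36407b89f897598bfbb9ea67b54c833df",
 "table3.tsv": "bf9b269355b555d1dd920385023b31fe200faa767a68944a22991b0c7fd50d0c",
 "table5.tsv": "b044dee4eeb88d1808320949bacf7f1d5fcba45822e99b42518168f1e7c208da",
 "table6.tsv": "218ee3e0c79989fac8ffe1f12c57dd0cb0a10b803d4429f89cbf73c93a36e34f",
 "fig3_tree.nwk": "604ca86e23fb7fcda2b008be7da7a9d69a731d412313936b325b95c358503465",
 "fig3_chars.tsv": "3cc77a7e16987ee907ecfcaf39d1376feacabf7d56a7cdbfaff71f3c80e5bea2"
}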