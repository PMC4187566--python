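0461d4b0e3c4da0afe3443f52db565517a2471b06e8838c7bdac2c2b210e37d4  table1.csv
a37968fd3e899da825bbefbdac712faeb4b13f982cc72ab01275fdd1a2911afd  table1_means.csv
ad0659feabb16149508c5b8129aa396826e63cb21ebc663c5ffc8c59d875ecc7  table2.csv
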