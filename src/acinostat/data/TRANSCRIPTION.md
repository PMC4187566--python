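# Transcription note

`table1.csv` holds the per-animal measurements for the eight young adult rats
(day 60): body weight, lung volume by water displacement, and per-lobe volumes
(RUL, RML, RLL, LC, LL). For the right middle lobe a second, Cavalieri-based
volume was measured on the tomographic dataset, from which the embedding
shrinkage percentage derives (paraffin for samples A–C, critical-point drying
for D–H).

`table1_means.csv` holds the published mean row of the same table at its
printed precision. The whole-lung acinar-number estimate was published from
these printed means together with the mean right-middle-lobe count of 686
acini, so the reproduction uses them verbatim; per-animal means recomputed
from `table1.csv` agree to the third significant digit.

`table2.csv` holds the lobe-validation summary: per-lobe mean acinar volume,
counted and estimated acinar numbers (mean ± SD over N = 3 animals per
remaining lobe, N = 8 for RML), t-test p-values, and matching accuracy
(estimated/counted × 100%).

SHA-256 checksums of the transcribed files are recorded in `CHECKSUMS.txt`
and verified by the test suite.
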