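"""Calibrate Karlin-Altschul constants on a simulated non-coding null.

Simulates non-coding alignment pairs (GC 40 %, 30 % divergence), scans
them exactly as real queries are scanned, and fits P = k N exp(-a S) to
the pooled segment-score distribution by log-linear regression.  The
fitted constants convert any segment score into a P-value.
"""

import numpy as np

import codonscan as cs

rng = np.random.default_rng(2)

training = cs.build_training_set(cs.CodingModel(n_codons=200), 500, rng)
matrix = cs.lod_from_counts(cs.count_codon_pairs(training), pseudocount=0.5)

# 40 sequences x 10 kb keeps this example fast; production calibration
# uses 100 x 100 kb (see scripts/acceptance.py)
null = cs.NullModel(gc_content=0.40, divergence=0.30, seq_length=10_000, n_sequences=40)
calib = cs.calibrate(null, matrix, rng=rng)

print(f"pooled null segments: {calib.n_segments}")
print(f"k = {calib.k:.4f}")
print(f"a = {calib.a:.4f}")
print(f"r^2 of log-linear fit = {calib.r_squared:.4f}")

print("\nscore -> P-value in a 10 kb search:")
for s in (5, 10, 15, 20, 25):
    print(f"  S = {s:>2}:  P = {cs.pvalue(s, 10_000, calib.k, calib.a):.3g}")

calib.save("calibration.json")
print("\nwrote calibration.json")
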