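"""Required read depth and artifact thresholds for junction detection.

How deep must RNA-Seq coverage be to detect a junction expressed at a
given allele fraction, and why does the pipeline demand five supporting
reads?
"""

from ncsplice import PowerParams, expected_artifact_reads, poisson_tail, required_depth

# Depth needed to call a junction at 10% allele fraction against a 5%
# null, with 5% false positives and 80% power (one-sided binomial,
# Gaussian approximation).
depth = required_depth(PowerParams(j0=0.05, j1=0.10, z_alpha=1.645, z_beta=0.84))
print(f"required depth for a 10% JAF at 80% power: {depth}x")

for j1 in (0.10, 0.20, 0.30, 0.50):
    d = required_depth(PowerParams(j0=0.05, j1=j1))
    print(f"  alternative JAF {j1:.2f} -> {d}x")

# At 200x and mean base quality 20, misaligned bases are expected to
# fake about 2 supporting reads; requiring 5 keeps the chance of a
# purely artifactual call near 5%.
lam = expected_artifact_reads(200, 20)
tail = poisson_tail(lam, 5)
print(f"expected artifact reads at 200x/Q20: {lam:g}")
print(f"P(>=5 artifact reads): {tail:.4f}  (~5% chance call)")
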