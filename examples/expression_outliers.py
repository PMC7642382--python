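"""Tukey-fence expression outliers for genes carrying splice mutations.

Given a gene x sample table of log2 expression, score the mutated
sample against the cohort: (x - Q3)/IQR above the third quartile,
(x - Q1)/IQR below the first; |score| > 1.5 flags an outlier.
"""

import numpy as np
import pandas as pd

from ncsplice.stats import outlier_table

rng = np.random.default_rng(7)
samples = [f"S{i:02d}" for i in range(40)]
expr = pd.DataFrame(
    rng.normal(8.0, 1.0, size=(3, 40)), index=["GENE_A", "GENE_B", "GENE_C"],
    columns=samples,
)
# GENE_A is strongly overexpressed in the mutated sample S00, GENE_B
# strongly reduced, GENE_C unchanged
expr.loc["GENE_A", "S00"] = expr.loc["GENE_A"].quantile(0.75) + 3.0
expr.loc["GENE_B", "S00"] = expr.loc["GENE_B"].quantile(0.25) - 3.0

results = outlier_table(expr, {"GENE_A": "S00", "GENE_B": "S00", "GENE_C": "S00"})
for r in results:
    score = "NA" if r.score is None else f"{r.score:+.2f}"
    print(f"{r.gene_id}: x={r.x:.2f} score={score} tail={r.tail} outlier={r.is_outlier}")
print("scores beyond +/-1.5 IQR mark expression outliers in the mutated sample")
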