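"""Test whether receptor/channel/secreted classes are over-represented
among aborally enriched genes.

Builds a toy annotation table (Pfam-style domain labels plus a
signal-peptide flag), classifies genes, and runs the one-sided Fisher
composition test of the aboral set against the oral set.
"""

import numpy as np
import pandas as pd

from planaxis.annotation import classify_genes, composition_test

rng = np.random.default_rng(0)
genes = [f"g{i:03d}" for i in range(300)]
domains = rng.choice(["7tm_1", "Ion_trans", "TauD", ""], size=300,
                     p=[0.1, 0.1, 0.1, 0.7])
ann = pd.DataFrame({
    "gene_id": genes,
    "domains": domains,
    "signal_peptide": (rng.random(300) < 0.2).astype(int),
})
classes = classify_genes(ann)

# aboral set deliberately enriched for GPCRs
aboral = {g for g, d in zip(genes, domains) if d == "7tm_1"} | set(genes[:20])
oral = set(genes[100:160]) - aboral
result = composition_test(aboral, oral, classes)
print(result.to_string(index=False))
print("aboral_pct/oral_pct are class percentages of each enriched set; "
      "p is the one-sided Fisher test of aboral over-representation.")
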