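"""Generate the synthetic benchmark dataset and check its realism.

Builds the default 30-protein batch (150-site Cα globules, 60-taxon Yule
trees, packing-driven site rates, JTT-simulated MSAs) and reports the
generator diagnostics that justify using it as a stand-in for real data:
the spread of packing densities across each globule and the strength of the
imposed rate-packing coupling before any inference is run.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sitevar.structure import compute_wcn
from sitevar.synth import generate_protein

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for p in range(30):
    prot = generate_protein(n_sites=150, n_taxa=60, seed=1000 * p)
    wcn = compute_wcn(prot.structure).values
    rows.append({
        "protein": p,
        "n_sites": prot.structure.n_sites,
        "n_taxa": prot.msa.n_rows,
        "wcn_p90_over_p10": np.quantile(wcn, 0.9) / np.quantile(wcn, 0.1),
        "corr_rate_neg_wcn": np.corrcoef(prot.true_rates, -wcn)[0, 1],
        "tree_length": prot.tree.total_length(),
        "mean_rate": prot.true_rates.mean(),
    })

df = pd.DataFrame(rows)
df.to_csv(OUT / "01_generator_diagnostics.tsv", sep="\t", index=False,
          float_format="%.4f")

print(f"generated {len(df)} synthetic proteins")
print(f"WCN 90/10 percentile ratio: mean {df.wcn_p90_over_p10.mean():.2f} "
      f"(packing spread across each globule)")
print(f"imposed rate/packing coupling rho(rate, -WCN): "
      f"mean {df.corr_rate_neg_wcn.mean():.3f}")
print(f"wrote {OUT / '01_generator_diagnostics.tsv'}")
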