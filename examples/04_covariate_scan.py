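"""Screen 19 bioclim-like covariates against leaf N with single-predictor PGLS.

In the synthetic data a latent latitude axis drives the "temperature"
covariates (bio1-bio11) and part of leaf N, while bio12-bio19 are pure
noise, so temperature-like variables should dominate the top of the scan.
"""

import pstoich as ps
from pstoich.pipeline import _match

tree, table = ps.generate_study_like_dataset(ps.SimConfig(seed=3))
tree, table = _match(tree, table)

covs = [c for c in table.columns if c.startswith("bio")]
scan = ps.covariate_scan(table["N"], table[covs], tree)
print(scan.summary.head(8).round(4).to_string(index=False))

top = scan.summary.head(5)["covariate"]
n_temperature = sum(int(c[3:]) <= 11 for c in top)
print(f"\ntemperature-like covariates among top 5: {n_temperature}/5")
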