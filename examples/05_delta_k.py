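"""Choose the number of ancestral clusters with Evanno's delta-K.

Admixture-model runs (e.g. STRUCTURE) are summarised as one log-likelihood
per (K, replicate); delta-K is the absolute second difference of the mean
likelihood divided by its replicate standard deviation, and peaks at the
best-supported K. Here a table with a likelihood elbow at K = 4 is built
and analysed.
"""

import numpy as np
import pandas as pd

from hybridplan import evanno_delta_k

rng = np.random.default_rng(1)
rows = []
for k in range(1, 9):
    mean_lnp = -50_000 + 6_000 * min(k, 4) - 150 * max(0, k - 4)
    for replicate in range(10):
        rows.append({"k": k, "replicate": replicate, "lnp": mean_lnp + rng.normal(0, 40)})

table = evanno_delta_k(pd.DataFrame(rows))
print(table.round(2).to_string())
print(f"\nbest-supported K = {table.attrs['best_k']}")
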