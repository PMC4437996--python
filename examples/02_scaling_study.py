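"""How the number of 1-1 rules grows with the number of attributes.

On iid random data the per-pair chance of passing the thresholds does not
depend on how many attributes there are, so the rule count grows with the
number of attribute pairs — quadratically.  The log-log slope of the
rule count against the attribute count is therefore ≈ 2.
"""

import numpy as np

from rqlnet import DiscoveryConfig, builtin_query, discover_11, run_query
from rqlnet.synthetic import GeneratorSpec, random_dataset

grid = [50, 100, 200, 400]
counts = []
for n_attrs in grid:
    ds = random_dataset(GeneratorSpec(seed=1, n_samples=20,
                                      n_attrs=n_attrs)).scale_center()
    query = builtin_query("Q1", ds)   # high/low co-expression template
    matrix = run_query(query, {ds.name: ds})
    rs = discover_11(matrix, DiscoveryConfig())
    counts.append(len(rs))
    print(f"{n_attrs:4d} attributes -> {len(rs):5d} rules")

slope = np.polyfit(np.log(grid), np.log(counts), 1)[0]
print(f"log-log slope: {slope:.3f} (quadratic growth -> 2)")
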