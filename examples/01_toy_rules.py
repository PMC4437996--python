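"""Mine exact rules from a small heterogeneous three-table database.

The toy database holds gene expression (gen), metabolite assays (met) and
sample annotation (ann) for six shared samples.  One query mixes three
predicates — a binary flag being set, a binary flag being clear, and a
quantitative value being high — and the miner returns the implications
that hold across the tables, joined row-wise by sample id.
"""

from rqlnet import (DiscoveryConfig, discover_11, parse_query, run_query,
                    toy_database)
from rqlnet.synthetic import TOY_QUERY

catalog = toy_database(seed=0)
query = parse_query(TOY_QUERY, catalog)
matrix = run_query(query, catalog)
print(f"{matrix.N} evaluation units × {len(matrix.columns)} labeled "
      f"attributes: {matrix.column_names}")

ruleset = discover_11(matrix, DiscoveryConfig(min_support=0.10,
                                              min_confidence=0.90))
print(f"{len(ruleset)} rules at support ≥ 0.10, confidence ≥ 0.90:")
for rule in ruleset:
    tag = "exact" if rule.exact else "approx"
    print(f"  {rule}  [{tag}]  support={rule.support:.3f} "
          f"confidence={rule.confidence:.3f} lift={rule.lift:.3f} "
          f"leverage={rule.leverage:.3f}")

# Both printed rules have confidence 1: whenever the A1 flag is set, the
# metabolite M2 exceeds 0.5, and whenever gene G3 is high, A1 is clear.
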