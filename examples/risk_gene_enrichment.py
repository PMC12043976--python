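"""One-tailed hypergeometric enrichment of a risk-gene set.

Reproduces the published worked fractions: with 7,921 of 22,280 genes
m6A-modified, 34 of 81 risk genes modified corresponds to 41.98% of the risk
set vs 35.55% of the universe; the upper-tail hypergeometric p quantifies
whether that excess could arise from drawing 81 genes at random.
"""

from epimn.enrichment import gene_set_enrichment
from epimn.genome import GeneSet

universe = [f"gene{i:05d}" for i in range(22280)]
modified = universe[:7921]
risk = modified[:34] + universe[7921:7968]  # 81 genes, 34 modified

result = gene_set_enrichment(
    GeneSet("m6a_modified", frozenset(modified)),
    GeneSet("ALS_risk", frozenset(risk)),
    GeneSet("expressed", frozenset(universe)),
)
report = result.report()
print(f"risk genes modified:     {result.k}/{result.n} "
      f"({report['percent_set']}%)")
print(f"universe modified:       {result.K}/{result.N} "
      f"({report['percent_universe']}%)")
print(f"one-tailed hypergeometric p = {result.p_upper:.3g}")
print("(p is the chance of seeing at least this many modified risk genes "
      "if the risk set were a random draw from the universe)")
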