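"""Quantify a simulated MPRA experiment and call active elements.

Simulates barcode-level counts for the full 624-element library under a
planted grammar (site-count effect + positional bonuses), then runs the
quantification recipe: count filters (RNA >= 3 in every replicate,
DNA >= 10), RPM scaling, RNA/DNA ratios per barcode, element means, basal
normalization, replicate averaging, and per-replicate Wilcoxon rank-sum
activity calls with Bonferroni correction.
"""

import numpy as np
from scipy.stats import spearmanr

from cisgrammar import mpra_quant as mq, simulate as sim
from cisgrammar.library_design import enumerate_syn_elements

elements = enumerate_syn_elements()
truth = sim.simulate_truth(elements, sim.default_grammar(), seed=5)
counts = sim.simulate_counts(truth.activity, sim.CountSimConfig(seed=6))
print(f"simulated {len(counts)} barcodes x (1 DNA + 3 RNA replicates)")

filtered = mq.filter_barcodes(counts)
print(f"barcodes surviving count filters: {len(filtered)}/{len(counts)}")

expr = mq.normalize_expression(filtered)
print(f"basal normalized expression (by construction): "
      f"{expr.loc['basal', 'expression']:.3f}")

est = expr.drop("basal").expression
rho = spearmanr(truth.activity.loc[est.index], est).statistic
print(f"Spearman(planted activity, estimated expression) = {rho:.3f}")

calls = mq.call_activity(mq.barcode_expression(filtered), n_tests=637)
print(f"elements called active vs basal in all replicates: "
      f"{calls.active.sum()}/{len(calls)} ({100 * calls.active.mean():.0f}%)")
# High recovery reflects experiment-scale sequencing depth (~20M DNA / 13M RNA
# reads) and 8 barcodes per element.
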