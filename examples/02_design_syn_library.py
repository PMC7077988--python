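"""Enumerate the synthetic library and assemble the oligo pool.

Builds every ordered arrangement of 2-4 distinct oriented binding sites
(624 elements), then assembles the full barcoded pool: each element x 8
barcodes plus 112 basal (minimal-promoter-only) oligos, all exactly 150 bp
with restriction-clean variable segments.
"""

import cisgrammar as cg
from cisgrammar.library_design import build_syn_pool, element_insert, enumerate_syn_elements

elements = enumerate_syn_elements()
by_k = {k: sum(1 for e in elements if e.k == k) for k in (2, 3, 4)}
print(f"elements: {len(elements)} total = "
      f"{by_k[2]} two-site + {by_k[3]} three-site + {by_k[4]} four-site")

blocks = cg.default_blocks()
example = elements[-1]  # a 4-mer; lower case = reverse orientation
print(f"\nexample element {example.element_id}: "
      f"[SEQ] insert is {len(element_insert(example, blocks))} bp of concatenated 20-bp blocks")

pool = build_syn_pool(elements, blocks, seed=0)
print(f"pool: {len(pool)} oligos "
      f"({len(elements)} x 8 barcodes + {sum(r.role == 'basal' for r in pool)} basal), "
      f"all {len(pool[0].oligo)} bp, {len({r.barcode for r in pool})} unique barcodes")
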