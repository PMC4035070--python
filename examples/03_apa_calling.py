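"""Call alternative polyadenylation sites from tag clusters.

Plants two poly(A) sites 500 bp apart used at 0.7/0.3, simulates 500 tags
around them (shear width 30 bp), and runs the peak caller; then shows the
200 bp resolution limit by moving the sites 100 bp apart.
"""

import numpy as np

from exprss import call_apa_sites

rng = np.random.default_rng(0)
n = 500
use_primary = rng.random(n) < 0.7
positions = np.where(
    use_primary,
    np.round(rng.normal(3000, 30, n)),  # annotated 3'-proximal site
    np.round(rng.normal(2500, 30, n)),  # upstream alternative site
).astype(int)

for call in call_apa_sites(positions, strand="+", gene_id="geneX"):
    print(f"{call.kind:11s} site at {call.position} "
          f"(support {call.support}, usage {call.fraction:.2f})")
# Both sites are recovered with usage close to the planted 0.7/0.3 split.

close = np.where(
    use_primary,
    np.round(rng.normal(3000, 30, n)),
    np.round(rng.normal(2900, 30, n)),
).astype(int)
calls = call_apa_sites(close, strand="+", gene_id="geneX")
print(f"sites 100 bp apart -> {len(calls)} call(s): tag peaks <200 bp apart "
      "cannot be distinguished under random shearing")
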