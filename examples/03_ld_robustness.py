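"""Why joint fitting matters: effect sizes under linkage disequilibrium.

Simulates 2-eQTL genes with the variant pair at increasing LD (r^2 from 0
to 0.8) and compares the joint estimator against the per-variant marginal
fit that ignores the partner eQTL.  The joint fit stays unbiased at every
LD level, while the marginal estimator absorbs the partner's effect and
its error grows with r^2.
"""

import numpy as np

from afckit import fit_afc, fit_afc_single, simulate_counts, simulate_haplotype_pair
from afckit.io_formats import HaplotypeDesign
from afckit.simulation import simulate_effects

rng = np.random.default_rng(11)
n, pairs = 839, 25

print(f"{'r^2':>5}{'joint bias':>12}{'marginal |err|':>16}")
for r2 in (0.0, 0.2, 0.4, 0.6, 0.8):
    jerr, merr = [], []
    for _ in range(pairs):
        s = simulate_effects(2, 1.0, rng)
        H1, H2 = simulate_haplotype_pair(0.3, 0.3, r2, n, rng)
        total, *_ = simulate_counts(H1, H2, s, np.log2(250.0), rng)
        yv = np.log2(total + 1.0)
        design = HaplotypeDesign(
            gene_id="g", variant_ids=["va", "vb"],
            sample_ids=[str(i) for i in range(n)],
            H1=H1.astype(float), H2=H2.astype(float),
        )
        jerr.extend(fit_afc(design, yv, compute_ci=False).s - s)
        for k in range(2):
            merr.append(abs(fit_afc_single(design, yv, variant_index=k).s[0] - s[k]))
    print(f"{r2:>5.1f}{np.mean(jerr):>+12.4f}{np.mean(merr):>16.3f}")
# Joint bias stays ~0 in every row; the marginal error column climbs with
# LD because correlated eQTLs are not conditionally adjusted for.
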