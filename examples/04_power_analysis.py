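"""Binomial power to resolve allelic imbalance at a given fold resolution.

Maps log2 aFC offsets to reference-allele ratios through the base-2 logit
link, then tabulates the power of the exact two-sided binomial test
(alpha = 0.01) to detect a 0.5- or 1-fold deviation from a balanced null
across read coverages — both by 1000-draw simulation and by exact
enumeration.
"""

from afckit import compute_power, ref_ratio_from_afc
from afckit.power import power_grid

print("fold resolution -> reference ratio (balanced null):")
for fc in (0.5, 1.0):
    hi, lo = ref_ratio_from_afc(fc), ref_ratio_from_afc(-fc)
    print(f"  +/-{fc}: {hi:.2f} / {lo:.2f}")

grid = power_grid(
    coverages=[20, 50, 100, 500], r0s=[0.5], fcs=[0.5, 1.0],
    alpha=0.01, n_sim=1000, seed=0,
)
grid["power_exact"] = [
    compute_power(int(c), 0.5, f, method="enumeration")
    for c, f in zip(grid["coverage"], grid["fc"])
]
print(grid[["coverage", "fc", "power", "power_exact"]].to_string(index=False))
# Power rises with coverage and with the fold resolution sought; the
# simulated column agrees with exact enumeration to Monte-Carlo accuracy.
# ~100 reads give near-complete power for a 1-fold (2x) imbalance but only
# partial power at 0.5-fold resolution.
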