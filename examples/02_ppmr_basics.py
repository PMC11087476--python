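"""Predator-prey mass ratio for a single stomach.

PPMR is predator body mass over the abundance-weighted mean prey mass in
its stomach, averaged on the linear gram scale before taking log10.
"""

from sizesel import compute_ppmr, weighted_mean_prey_mass

# a 10 g lanternfish that ate 2 copepods of 0.1 g and 3 amphipods of 0.2 g
mean_prey = weighted_mean_prey_mass(counts=[2, 3], masses_g=[0.1, 0.2])
print(f"abundance-weighted mean prey mass: {mean_prey:.3f} g")

summary = compute_ppmr(predator_mass_g=10.0, mean_prey_g=mean_prey)
print(f"PPMR        = {summary['ppmr']:.1f}")
print(f"log10 PPMR  = {summary['log10_ppmr']:.5f}")
print()
print("A PPMR of 62.5 means the predator is 62.5 times heavier than its")
print("average prey item; the log10 value is the response analysed against")
print("temperature downstream.")
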