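"""Statistical comparison of two trajectory variants.

Compares a geometry series between two models with the windowed
Mann-Whitney Z statistic (50-snapshot bins), tests variances with a
two-sided F-test, and controls a declared family of parameters with the
Benjamini-Hochberg false-discovery-rate step-up.
"""

import numpy as np

import fpgtraj as F
from fpgtraj.census import catalytic_series

toy = F.build_toy_complex()

def series_for(fraction, seed):
    plan = F.PlantSpec(census=F.CensusPlant(fraction=fraction),
                       noise_sigma=0.05, seed=seed)
    traj, _ = F.simulate_trajectory(toy, plan, 500)
    return catalytic_series(traj, toy.catalytic_atoms())

# model "C" docks the nucleophile most of the time, model "A" rarely
bundle_c = series_for(0.8, 41)
bundle_a = series_for(0.1, 42)

cmp_ = F.moving_mwz(bundle_c["d1"], bundle_a["d1"], window=50)
n_sig = int(np.sum(np.abs(cmp_.z) > 3))
print(f"moving MWZ on d1 (N...C1'): {len(cmp_)} bins of 50 snapshots, "
      f"{n_sig} bins with |Z| > 3")
print("Bins with large |Z| mark stretches where the two models sample")
print("visibly different distance distributions.")

r = F.f_test_variance(bundle_c["d1"], bundle_a["d1"])
print(f"\nF-test on d1 variances: F = {r.f:.2f} "
      f"(larger variance in {r.larger}), p = {r.p:.2e}")

pairs = {name: (bundle_c[name], bundle_a[name])
         for name in ("d1", "d2", "angle1", "angle2")}
fam = F.compare_parameter_family(pairs, q=0.05, test="f")
print("\nBH-corrected family of variance tests (q = 0.05):")
print(fam.round(4).to_string())
print("Only d1 and angle-coupled parameters moved by the census plant")
print("should survive the correction; d2 is identical by construction.")
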