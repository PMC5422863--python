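"""Hydrogen-bond occupancy analysis across two model variants.

Detects every hydrogen bond (10-12 potential with cos^4 angular weight,
existence = energy > 1.2 kcal/mol) in each snapshot, tabulates per-bond
occupancies, classifies their stability, and screens for bonds that
distinguish the two groups of models at the > 3 sigma + 0.10 rule.
"""

import numpy as np

import fpgtraj as F

toy = F.build_toy_complex(n_hbond_stations=3)

def run(seed, differential):
    """One 'model': the third plant is the group-distinguishing bond."""
    plan = F.PlantSpec(
        hbonds=[F.HBondPlant(0.95), F.HBondPlant(0.30),
                F.HBondPlant(0.90 if differential else 0.15)],
        noise_sigma=0.05, seed=seed)
    traj, _ = F.simulate_trajectory(toy, plan, 400)
    return traj

trajs = {f"C{i}": run(100 + i, True) for i in range(2)}
trajs.update({f"A{i}": run(200 + i, False) for i in range(2)})

table = F.occurrence_table(trajs)
labeled = table.labeled(toy.topology)
print("occupancy table (fraction of snapshots; bonds below 1% everywhere "
      "are dropped):")
print(labeled.round(3).to_string())

stability = F.classify_stability(table.occurrence.mean(axis=1))
print("\nstability classes (stable > 90%, fluctuating <= 25%):")
for key, cls in stability.items():
    print(f"  {toy.topology.atom_label(key.donor)} -> "
          f"{toy.topology.atom_label(key.acceptor)}: {cls}")

phi, contingency, _ = F.phi_coefficient(table.occurrence["C0"],
                                        table.occurrence["C1"])
print(f"\nphi coefficient between the two C replicates: {phi:.2f} "
      f"(1 = identical stable/unstable membership)")

dm = F.group_specific_bonds(table, {m: m[0] for m in trajs})
print("\ngroup-specific bonds (|mean_C - mean_A| > 3 sigma and > 0.10):")
for key, row in dm.selected.iterrows():
    print(f"  {toy.topology.atom_label(key.donor)} -> "
          f"{toy.topology.atom_label(key.acceptor)}: "
          f"C {row[f'mean_C']:.2f} vs A {row[f'mean_A']:.2f}")
print("Only the planted differential bond should appear: occupancy "
      "differences of this size cannot arise from replicate scatter.")
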