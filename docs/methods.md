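# Methods

This note records the models, conventions and numerical choices behind
fpgtraj, and what the synthetic-data validation does and does not
demonstrate.

## Scope and data model

The package analyses coordinate ensembles of protein–DNA–water complexes:
a `Topology` (atoms grouped into residues with classes protein / dna /
water / ion / other and donor/acceptor annotations) plus a `Trajectory`
(snapshots × atoms × 3, Å, with a snapshot spacing in ps; the simulations
this toolkit targets save one frame per 2 ps, 5000 frames per 10 ns run).
Multi-model PDB is the interchange format: one snapshot per MODEL record.
Alternate locations collapse to the highest-occupancy conformer (ties
prefer 'A'); elements are inferred from atom names by PDB v3 rules when
the element column is blank; residue numbering is taken verbatim from the
file (any linearized reporting index is a display-time mapping). Donor
hydrogens are located geometrically (≤ 1.2 Å from the donor heavy atom),
so the same residue templates serve hydrogen-bearing MD snapshots and
hydrogen-free crystal structures; in the latter case detection falls back
to a heavy-atom mode (below).

## Hydrogen-bond model

A bond between donor D (hydrogen H) and acceptor A scores

    E = −ε · [5 (σ/d)¹² − 6 (σ/d)¹⁰] · cos⁴θ,   clamped at ≥ 0,

with d the D…A heavy-atom distance, θ the deviation of D–H…A from linear,
ε = 2.8 kcal/mol and σ = 2.9 Å (the well depth is reached at d = σ with a
linear bond). The angular factor is set to zero for θ > 90°; without the
clamp a hydrogen pointing directly away from the acceptor would score
maximally. A bond *exists* in a snapshot when E > 1.2 kcal/mol, which for
a linear bond corresponds to roughly 2.7 Å < d < 3.45 Å. Donors with two
hydrogens score each and keep the best. In heavy-atom mode (no hydrogens
in the model) the angular factor uses the deviation of the
antecedent–D…A angle from tetrahedral (109.5°), or 1 if no bonded heavy
neighbour exists. A purely geometric fallback criterion (d ≤ 3.5 Å,
D–H…A ≥ 120°) is provided and agrees with the energy criterion on planted
ideal/broken geometries.

Detection evaluates every donor/acceptor pair within a 5 Å neighbour
cutoff (KD-tree accelerated; the test suite asserts exact set equality
with an all-pairs scalar reference on randomized snapshots). Pairs within
one residue are excluded by default. Bonds are keyed by donor/acceptor
heavy atoms so occurrence tables are comparable across protonation-state
variants of the same system (e.g. a neutral versus charged Glu carboxyl).

Occupancy statistics follow the standard workflow: per-model occurrence
fractions with a 1 %-of-snapshots existence floor; stability classes
stable (> 0.90), fluctuating (≤ 0.25, boundary inclusive), intermediate;
φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)) on the 2×2 stable-membership table
(0 with a flag when a margin is empty); group-difference maps selecting
bonds with |Δ mean occurrence| > k·σ (k = 3) *and* above an absolute floor
(0.10, suppressing sparse-bond noise), where σ is the pooled within-group
standard deviation across models — an across-pairs mode is available
because "3σ over all pairs of models" admits both readings. Replicate
reproducibility reports per-bond mean and coefficient of variation.

## Water bridges

A bridge exists when one water is simultaneously H-bonded (same criterion)
to two or three non-water partners; a water with k partners contributes
all C(k,2) pairs and C(k,3) triplets. A partner set is counted once per
snapshot however many waters bridge it, with the multiplicity kept in a
histogram — a pair persistently bridged by *two* waters is reported as its
own phenomenon rather than a doubled count. Chemically equivalent partner
atoms merge by default (Glu Oε1/Oε2, Asp Oδ1/Oδ2 → one carboxylate
partner; phosphate O1P/O2P merging optional). Retention uses the
lowest-quartile rule: keep the records that collectively account for
> 75 % of all occurrences, computed separately for pairs and triplets
(level set: ties at the cutoff stay together); the equivalent fixed
cutoffs are 2000 (pairs) and 1500 (triplets) per 5000 snapshots, rescaled
linearly for other trajectory lengths.

## Geometry conventions

* Torsions are signed, IUPAC convention, reported in (−180°, +180°].
  Under full atom reversal the IUPAC torsion keeps its value (the sign is
  defined to be viewing-direction independent), and the tests assert that
  symmetry. A degenerate central axis masks the value rather than raising.
* Glycosidic χ is O4'–C1'–N9–C4 (purines) / O4'–C1'–N1–C2 (pyrimidines);
  for carbacyclic analogues the atom isosteric to O4' is used. Conformer
  domains: syn = (−90°, +90°) with the boundary assigned to anti
  (half-open convention); the border sub-ranges high-anti (−90°, −30°] and
  high-syn (60°, 120°] are reported alongside the primary label because
  the structural literature uses them for χ values straddling the divide.
  All boundaries are configurable.
* Kabsch superposition is the SVD solution with the determinant
  correction (proper rotation guaranteed); collinear point sets are an
  error. r.m.s.d. series superpose each snapshot on a fit selection and
  measure over a second selection.
* DNA kink: each arm is an ordered set of P atoms (both strands' P per
  base pair recommended); the arm axis is the least-squares linear trend
  of P position against order — a raw principal component is dominated by
  the *lateral* spread of helical phosphates over a half-turn arm, whereas
  the order-weighted trend cancels the helical phase when both strands are
  included and is oriented 5'→3' automatically. The kink is the angle
  between the two oriented axes: 0° for straight DNA, ~60° for the sharp
  glycosylase-induced bend. Default arms: 6 bp per side excluding ±1
  around the lesion. Absolute values are convention-relative, as for any
  kink definition.
* Propeller twist: base normals from least-squares ring planes, measured
  about the pair long axis (purine C8 → pyrimidine C6; centroid axis for
  like-type pairs), with the first base's normal oriented by the chirality
  of its glycosidic attachment so the sign is deterministic.
* Base eversion is a configurable four-point pseudo-dihedral (default:
  base ring centroid, lesion C1', lesion P, 3'-neighbour P). Values are
  comparable only within one definition.
* SASA is Shrake–Rupley with a deterministic golden-section spiral point
  set (no RNG; 960 points default, < 0.5 % single-sphere quadrature error)
  over a bundled Bondi van-der-Waals radius table, probe 1.4 Å. Water
  burial = SASA(water in complex)/SASA(isolated water), buried ⇔ < 0.10.
  Occluded area between groups A and B is the mean of the two groups'
  buried-by-the-other areas with only the two groups present.
* Moving averages are centred, window 50 by default, and circular
  (vector) for angular series so ±179° averages to ±180°, not 0°.

## Trajectory statistics

Windowed Mann–Whitney Z compares two aligned series in disjoint
50-snapshot bins (sliding windows available): U from midranks,
Z = (U − nm/2)/σ_U with the tie-corrected σ_U, two-sided normal p. The
extreme of the statistic is (nm/2)/σ_U = √(3nm/(n+m+1)). The variance
F-test puts the larger sample variance in the numerator (recorded) with a
two-sided p; Benjamini–Hochberg step-up (statsmodels-backed,
cross-checked against a direct evaluation) controls a caller-declared
family of parameters — which series enter one family is a scientific
choice the package does not make. Snapshots within a bin are treated as
exchangeable; MD frames are autocorrelated, so p-values are
anticonservative for strongly correlated series. No effective-sample-size
correction is applied; this is a documented caveat.

## pH–activity model

activity(pH) = B + A/(1 + 10^(pKa − pH)) — one titratable group, rising
with pH, passing through B + A/2 at pH = pKa. Nonlinear least squares
(scipy `curve_fit`), initialized at B = min, A = range, pKa = half-range
crossing by linear interpolation, with ±1/±2 pH-unit restarts on failure;
standard errors from the Jacobian covariance. A fit with SE(pKa) > 1 pH
unit is flagged unidentifiable (data not bracketing the transition). The
module is validated by simulation: the printed literature value
pKa = 6.8 ± 0.1 serves as the planted anchor and uncertainty scale, not
as a fit target.

## Synthetic data: what it emulates, what it does not

The toy complex is a kinked (default 60°) idealized duplex — 14 bp,
labels −7…+6, central 8-oxoguanine lesion opposite C or A, bases built
from regular fused polygons with the glycosidic attachment on the internal
ring-bond bisector (≈ 126° to both ring neighbours, avoiding a
near-collinear torsion frame), χ set exactly by construction — plus a
protein scaffold (Pro1/Glu2-like dyad placed in the optimal attack
geometry, Arg/Phe stand-ins, filler), waters, a Zn²⁺ ion, and spatially
isolated plant stations. Plausibility means bonded distances in
1.0–1.8 Å, not force-field geometry; the toy protein is a geometric
scaffold, not a folded domain — sufficient because every downstream
analysis is geometry- and topology-driven.

Plants are realized by two-state Markov chains (stationary occupancy =
target, correlation time default 10 snapshots — occupancy traces of real
trajectories show persistence, so i.i.d. toggling would be an unrealistic
best case). Hydrogen-bond plants translate the acceptor-side residue
rigidly between an on-station at 3.05 Å (linear) and a broken station at
6.0 Å: 3.05 Å centres the on-state in the detection window, because the
10–12 well's repulsive wall lies only ~0.25 Å inside the 2.9 Å optimum
and an on-state planted exactly at the optimum loses ~9 % of snapshots to
the short-range clamp under 0.1 Å coordinate noise. Bridge stations place
partner carbonyls/hydroxyls so every planted contact is exactly linear
(waters donate to two carbonyl partners; a third partner donates to the
water), and toggle by parking the water 26 Å away. The χ process rotates
the lesion base about the C1'–N9 axis; the census plant shuttles the
whole Pro1 stand-in along the attack line (d1 = 3.5 ↔ 5.5 Å, angles
unchanged). Gaussian noise (default σ = 0.05 Å per coordinate) is added
last; everything is reproducible from the seed, and the manifest records
each plant's state in every snapshot.

At σ = 0 every planted event is detected exactly and manifests match
detector counts; at σ = 0.1 Å recovered occupancies stay within 0.03 of
targets. Passing these tests shows the *analysis machinery* is correct
and calibrated — it does not show that any force field, sampling protocol
or real trajectory satisfies the models' assumptions, and the planted
geometries are cleaner than real hydrogen-bond ensembles (no competing
acceptors, no correlated partner motion).

## Problem sizes used in validation

The standard validation trajectory is 5000 snapshots (the full 10-ns
cadence) with 20 hydrogen-bond plants spanning occupancies 0.05–0.95 and
5 bridge plants; oracle-equivalence checks run on 100 randomized
snapshots; statistical calibration uses 10⁴ null replicates; the pH fit
uses 200 noisy replicates of an 11-point curve. The group-difference
screen is additionally exercised on occurrence *tables* (200 background
bonds, 8 models, replicate scatter σ = 0.02) because the selection rule
consumes tables, and a table-level background exercises its false-positive
behaviour across many more bonds than geometric planting would.

## Known limitations

* The H-bond energy function is a documented surrogate for the (unpublished)
  function of the original trajectory-analysis tooling; occupancies near
  the 1.2 kcal/mol threshold are criterion-relative.
* Kink, eversion and occluded-area values are definition-relative;
  compare only within one configuration.
* No autocorrelation correction in the statistics module (above).
* The PDB writer emits the common fixed-column dialect only (no hybrid-36
  serials, no mmCIF); residue numbers must fit −999…9999.
* `group_specific_bonds` supports exactly two groups; multi-group designs
  are run pairwise.
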