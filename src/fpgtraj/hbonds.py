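"""Hydrogen-bond detection and cross-model occurrence statistics.

A bond "exists" in a snapshot when its stabilization energy exceeds a
threshold (default 1.2 kcal/mol).  The energy is a 10-12 Lennard-Jones-type
radial well with a cos^4 angular weight on the donor-hydrogen-acceptor
alignment:

    E = -eps * [5 (sigma/d)^12 - 6 (sigma/d)^10] * cos^4(theta)

with d the donor-acceptor heavy-atom distance, theta the deviation of
D-H...A from linear (the angular factor is zero beyond 90 degrees),
eps = 2.8 kcal/mol (the well depth, reached at d = sigma = 2.9 Angstrom
with a linear bond).  For structures without hydrogens a heavy-atom mode
scores the deviation of the antecedent-donor-acceptor angle from
tetrahedral.  Bonds are keyed by donor/acceptor heavy atoms so occurrence
tables are comparable across protonation-state variants of the same system.

Downstream statistics follow the occupancy-analysis workflow: per-model
occurrence tables (existence floor 1% of snapshots), stability classes
(stable > 90%, fluctuating <= 25%), phi contingency coefficients between
models, group-difference maps with a > 3 sigma selection rule, replicate
coefficients of variation, and recovery of crystal-structure reference
bonds.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .topology import Topology, Trajectory


class HBondKey(NamedTuple):
    """Donor/acceptor heavy-atom pair identifying one hydrogen bond."""

    donor: int
    acceptor: int


@dataclass
class HBondParams:
    epsilon: float = 2.8        # kcal/mol, well depth
    sigma: float = 2.9          # Angstrom, optimum donor-acceptor distance
    threshold: float = 1.2      # kcal/mol, existence criterion
    cutoff: float = 5.0         # Angstrom, donor-acceptor neighbor search
    exclude_same_residue: bool = True
    criterion: str = "energy"   # "energy" or "geometric" fallback
    geometric_distance: float = 3.5   # Angstrom (fallback criterion)
    geometric_angle: float = 120.0    # degrees D-H...A (fallback criterion)


def hbond_energy(donor_xyz, hydrogen_xyz, acceptor_xyz,
                 params: HBondParams | None = None,
                 antecedent_xyz=None) -> np.ndarray | float:
    """Stabilization energy (kcal/mol, >= 0) of donor...acceptor geometry.

    ``hydrogen_xyz`` may be None (heavy-atom mode): the angular factor then
    comes from the antecedent-donor-acceptor angle measured against the
    tetrahedral ideal, or is 1 when no antecedent is given.
    """
    p = params or HBondParams()
    d_xyz = np.asarray(donor_xyz, dtype=float)
    a_xyz = np.asarray(acceptor_xyz, dtype=float)
    d = np.linalg.norm(a_xyz - d_xyz, axis=-1)
    with np.errstate(divide="ignore"):
        x = p.sigma / np.maximum(d, 1e-9)
    radial = -p.epsilon * (5.0 * x ** 12 - 6.0 * x ** 10)
    if hydrogen_xyz is not None:
        h_xyz = np.asarray(hydrogen_xyz, dtype=float)
        theta = 180.0 - _angle(d_xyz, h_xyz, a_xyz)
    elif antecedent_xyz is not None:
        theta = np.abs(_angle(np.asarray(antecedent_xyz, dtype=float),
                              d_xyz, a_xyz) - 109.5)
    else:
        theta = np.zeros_like(d)
    ang = np.where(theta < 90.0, np.cos(np.radians(theta)) ** 4, 0.0)
    e = np.maximum(radial * ang, 0.0)
    return float(e) if np.ndim(e) == 0 else e


def _angle(a, b, c):
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", u, v) / np.maximum(nu * nv, 1e-12)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_hbonds(snapshot: np.ndarray, topology: Topology,
                  params: HBondParams | None = None,
                  return_energies: bool = False):
    """All donor-acceptor pairs bonded in one snapshot.

    Every donor/acceptor pair within the neighbor cutoff is evaluated
    (KD-tree accelerated but exactly equivalent to all-pairs); a bond is
    returned iff its energy exceeds the threshold (or, for the geometric
    fallback criterion, distance <= 3.5 A and D-H...A >= 120 degrees).
    Donors with several hydrogens score each and keep the best.
    """
    p = params or HBondParams()
    xyz = np.asarray(snapshot, dtype=float)
    donors = topology.donors
    acceptors = topology.acceptors
    if not donors or acceptors.size == 0:
        return ({}, {}) if return_energies else set()
    d_heavy, hyd_flat, hyd_off, nh, ante = _donor_arrays(topology, xyz)

    tree = cKDTree(xyz[acceptors])
    neigh = tree.query_ball_point(xyz[d_heavy], p.cutoff)
    counts = np.fromiter((len(x) for x in neigh), dtype=int,
                         count=len(neigh))
    di = np.repeat(np.arange(len(donors)), counts)
    if di.size == 0:
        return ({}, {}) if return_energies else set()
    aj = np.concatenate([np.asarray(x, dtype=int)
                         for x in neigh if len(x)])
    ai = acceptors[aj]
    dh = d_heavy[di]
    keep = ai != dh
    if p.exclude_same_residue:
        keep &= topology.residue_index[ai] != topology.residue_index[dh]
    di, ai, dh = di[keep], ai[keep], dh[keep]
    if di.size == 0:
        return ({}, {}) if return_energies else set()

    dist = np.linalg.norm(xyz[ai] - xyz[dh], axis=1)
    # per-pair best D-H...A deviation from linear (degrees); pairs whose
    # donor carries no hydrogen fall back to the antecedent angle
    nh_pair = nh[di]
    best_ang = np.zeros(di.size)  # cos^4 factor, filled below
    has_h = nh_pair > 0
    if has_h.any():
        pidx = np.flatnonzero(has_h)
        reps = nh_pair[pidx]
        rep = np.repeat(pidx, reps)
        within = np.arange(rep.size) - np.repeat(np.cumsum(reps) - reps, reps)
        hyd = hyd_flat[hyd_off[di[rep]] + within]
        theta = 180.0 - _angle(xyz[dh[rep]], xyz[hyd], xyz[ai[rep]])
        fac = np.where(theta < 90.0, np.cos(np.radians(theta)) ** 4, 0.0)
        np.maximum.at(best_ang, rep, fac)
    if (~has_h).any():
        pidx = np.flatnonzero(~has_h)
        an = ante[di[pidx]]
        fac = np.ones(pidx.size)
        with_ante = an >= 0
        if with_ante.any():
            sub = pidx[with_ante]
            theta = np.abs(_angle(xyz[ante[di[sub]]], xyz[dh[sub]],
                                  xyz[ai[sub]]) - 109.5)
            fac[with_ante] = np.where(theta < 90.0,
                                      np.cos(np.radians(theta)) ** 4, 0.0)
        best_ang[pidx] = fac

    if p.criterion == "geometric":
        ok = dist <= p.geometric_distance
        if has_h.any():
            ang_ok = np.zeros(di.size, dtype=bool)
            pidx = np.flatnonzero(has_h)
            reps = nh_pair[pidx]
            rep = np.repeat(pidx, reps)
            within = np.arange(rep.size) - np.repeat(np.cumsum(reps) - reps,
                                                     reps)
            hyd = hyd_flat[hyd_off[di[rep]] + within]
            good = _angle(xyz[dh[rep]], xyz[hyd], xyz[ai[rep]]) \
                >= p.geometric_angle
            np.logical_or.at(ang_ok, rep, good)
            ok &= ang_ok | ~has_h
        score = ok.astype(float)
    else:
        with np.errstate(divide="ignore"):
            x = p.sigma / np.maximum(dist, 1e-9)
        radial = -p.epsilon * (5.0 * x ** 12 - 6.0 * x ** 10)
        score = np.maximum(radial * best_ang, 0.0)

    found = {HBondKey(int(d), int(a)): float(s)
             for d, a, s in zip(dh, ai, score)}
    cutoff = 0.0 if p.criterion == "geometric" else p.threshold
    hits = {k: v for k, v in found.items() if v > cutoff}
    if return_energies:
        return hits, found
    return set(hits)


def _donor_arrays(topology: Topology, xyz: np.ndarray):
    """CSR-packed donor hydrogens plus per-donor antecedent indices,
    cached on the topology (bonded neighbors do not change between
    snapshots)."""
    cache = getattr(topology, "_hbond_arrays", None)
    if cache is not None and cache[0] == len(topology.donors):
        return cache[1]
    donors = topology.donors
    d_heavy = np.array([d.heavy for d in donors], dtype=int)
    nh = np.array([len(d.hydrogens) for d in donors], dtype=int)
    hyd_flat = np.array([h for d in donors for h in d.hydrogens], dtype=int)
    hyd_off = np.concatenate([[0], np.cumsum(nh)[:-1]])
    ante = np.full(len(donors), -1, dtype=int)
    for i, d in enumerate(donors):
        if not d.hydrogens:
            a = _nearest_heavy_neighbor(xyz, topology, d.heavy)
            ante[i] = -1 if a is None else a
    arrays = (d_heavy, hyd_flat, hyd_off, nh, ante)
    topology._hbond_arrays = (len(donors), arrays)
    return arrays


def _pair_score(xyz, topology, donor, acceptor: int, p: HBondParams):
    dpos = xyz[donor.heavy]
    apos = xyz[acceptor]
    if p.criterion == "geometric":
        d = np.linalg.norm(apos - dpos)
        if d > p.geometric_distance:
            return 0.0
        if donor.hydrogens:
            ang = max(_angle(dpos, xyz[h], apos) for h in donor.hydrogens)
            return 1.0 if ang >= p.geometric_angle else 0.0
        return 1.0
    if donor.hydrogens:
        return max(hbond_energy(dpos, xyz[h], apos, p) for h in donor.hydrogens)
    ante = _nearest_heavy_neighbor(xyz, topology, donor.heavy)
    return hbond_energy(dpos, None, apos, p,
                        antecedent_xyz=None if ante is None else xyz[ante])


def _nearest_heavy_neighbor(xyz, topology: Topology, heavy: int) -> int | None:
    res = topology.residues[topology.residue_index[heavy]]
    best, best_d = None, np.inf
    for i in res.atom_indices:
        if i == heavy or topology.elements[i] == "H":
            continue
        d = np.linalg.norm(xyz[i] - xyz[heavy])
        if d < best_d and d <= 1.8:
            best, best_d = int(i), d
    return best


# ---------------------------------------------------------------------------
# occurrence tables

@dataclass
class OccurrenceTable:
    """Per-bond, per-model fraction of snapshots in which the bond exists."""

    occurrence: pd.DataFrame          # index: HBondKey, columns: model labels
    n_snapshots: dict[str, int]
    existence_floor: float = 0.01

    @property
    def bonds(self) -> list[HBondKey]:
        return list(self.occurrence.index)

    @property
    def models(self) -> list[str]:
        return list(self.occurrence.columns)

    def labeled(self, topology: Topology) -> pd.DataFrame:
        """Occurrence table with human-readable chain:resnum:resname:atom ids."""
        out = self.occurrence.copy()
        out.index = [f"{topology.atom_label(k.donor)}--"
                     f"{topology.atom_label(k.acceptor)}" for k in out.index]
        return out


def occurrence_table(trajectories, existence_floor: float = 0.01,
                     params: HBondParams | None = None) -> OccurrenceTable:
    """Build the bond-occurrence table across trajectories (one per model or
    replicate run).  ``trajectories`` is a mapping label -> Trajectory or a
    sequence (labels default to traj.label / run index).  Bonds below the
    existence floor in every model are dropped."""
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not isinstance(trajectories, dict):
        trajectories = {t.label or f"run{i}": t
                        for i, t in enumerate(trajectories)}
    if not trajectories:
        raise ValueError("need at least one trajectory")
    tops = {id(t.topology) for t in trajectories.values()}
    sizes = {t.topology.n_atoms for t in trajectories.values()}
    if len(tops) > 1 and len(sizes) > 1:
        raise ValueError("trajectories have mismatched topologies")
    p = params or HBondParams()
    columns = {}
    n_snapshots = {}
    for label, traj in trajectories.items():
        counts: Counter = Counter()
        for si in range(traj.n_snapshots):
            counts.update(detect_hbonds(traj.coords[si], traj.topology, p))
        n_snapshots[label] = traj.n_snapshots
        columns[label] = {k: c / traj.n_snapshots for k, c in counts.items()}
    all_keys = sorted(set().union(*(c.keys() for c in columns.values())))
    # an object index keeps HBondKey entries intact (pandas would otherwise
    # tupleize them into a MultiIndex)
    idx = pd.Index(all_keys, dtype=object, tupleize_cols=False, name="bond")
    df = pd.DataFrame({label: [col.get(k, 0.0) for k in all_keys]
                       for label, col in columns.items()}, index=idx)
    if len(df):
        df = df.loc[(df > existence_floor).any(axis=1)]
    return OccurrenceTable(df, n_snapshots, existence_floor)


STABLE, INTERMEDIATE, FLUCTUATING = "stable", "intermediate", "fluctuating"


def classify_stability(occurrence, stable_above: float = 0.90,
                       fluctuating_below_or_at: float = 0.25):
    """Stability class per occurrence value: stable for > 90%, fluctuating
    for <= 25% (boundary inclusive), intermediate otherwise.  Accepts a
    scalar, Series/DataFrame or an OccurrenceTable."""
    if isinstance(occurrence, OccurrenceTable):
        occurrence = occurrence.occurrence
    vals = occurrence
    if np.ndim(vals) == 0:
        v = float(vals)
        if v > stable_above:
            return STABLE
        return FLUCTUATING if v <= fluctuating_below_or_at else INTERMEDIATE
    arr = np.asarray(vals, dtype=float)
    out = np.where(arr > stable_above, STABLE,
                   np.where(arr <= fluctuating_below_or_at,
                            FLUCTUATING, INTERMEDIATE))
    if isinstance(vals, pd.DataFrame):
        return pd.DataFrame(out, index=vals.index, columns=vals.columns)
    if isinstance(vals, pd.Series):
        return pd.Series(out, index=vals.index)
    return out


def phi_coefficient(occurrence_a: pd.Series, occurrence_b: pd.Series,
                    in_category: Callable[[float], bool] | None = None
                    ) -> tuple[float, np.ndarray, bool]:
    """Pearson mean-square contingency coefficient between two models.

    Bonds are cross-tabulated by membership in a binary category (default:
    stable, occurrence > 0.90) in model A vs model B.  Returns
    (phi, 2x2 table [[a, b], [c, d]], degenerate_flag); phi is 0 with the
    flag set when any table margin is empty.
    """
    if not occurrence_a.index.equals(occurrence_b.index):
        raise ValueError("occurrence series must share one bond universe")
    if len(occurrence_a) == 0:
        raise ValueError("empty bond universe")
    if in_category is None:
        in_category = lambda occ: occ > 0.90
    ca = occurrence_a.map(in_category).to_numpy(dtype=bool)
    cb = occurrence_b.map(in_category).to_numpy(dtype=bool)
    a = int(np.sum(ca & cb))
    b = int(np.sum(ca & ~cb))
    c = int(np.sum(~ca & cb))
    d = int(np.sum(~ca & ~cb))
    table = np.array([[a, b], [c, d]])
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, table, True
    return (a * d - b * c) / np.sqrt(denom), table, False


@dataclass
class DifferenceMap:
    """Group-difference map over bonds: mean occurrence per group, the
    difference, the dispersion estimate and the selection flag."""

    entries: pd.DataFrame
    groups: tuple[str, str]
    k: float
    absolute_floor: float

    @property
    def selected(self) -> pd.DataFrame:
        return self.entries[self.entries["selected"]]

    def residue_matrix(self, topology: Topology,
                       residue_order: list | None = None) -> pd.DataFrame:
        """Square signed-difference matrix over residues (linearized index),
        for difference-map plotting; entry (i, j) is the largest-magnitude
        selected bond difference between residues i and j."""
        residues = residue_order or topology.residues
        pos = {id(r): i for i, r in enumerate(residues)}
        n = len(residues)
        mat = np.zeros((n, n))
        for key, row in self.selected.iterrows():
            ri = pos[id(topology.residues[topology.residue_index[key.donor]])]
            rj = pos[id(topology.residues[topology.residue_index[key.acceptor]])]
            if abs(row["difference"]) > abs(mat[ri, rj]):
                mat[ri, rj] = mat[rj, ri] = row["difference"]
        labels = [f"{r.chain_id}:{r.number}" for r in residues]
        return pd.DataFrame(mat, index=labels, columns=labels)


def group_specific_bonds(table: OccurrenceTable, grouping: dict[str, str],
                         k: float = 3.0, absolute_floor: float = 0.10,
                         sigma_mode: str = "pooled") -> DifferenceMap:
    """Bonds whose occurrence differs between two model groups by more than
    ``k`` dispersions and an absolute floor.

    ``grouping`` maps model label -> group label (exactly two groups).  The
    dispersion is, per bond, the pooled within-group standard deviation of
    occurrences across models (``sigma_mode="pooled"``) or the sd over all
    per-pair differences (``sigma_mode="across_pairs"``).  A group with a
    single model borrows sigma from the other group with a warning.
    """
    groups = sorted(set(grouping.values()))
    if len(groups) != 2:
        raise ValueError("grouping must define exactly two groups")
    g1 = [m for m in table.models if grouping.get(m) == groups[0]]
    g2 = [m for m in table.models if grouping.get(m) == groups[1]]
    if not g1 or not g2:
        raise ValueError("each group needs at least one model in the table")
    occ = table.occurrence
    m1 = occ[g1].mean(axis=1)
    m2 = occ[g2].mean(axis=1)
    diff = m1 - m2
    v1 = occ[g1].var(axis=1, ddof=1) if len(g1) > 1 else None
    v2 = occ[g2].var(axis=1, ddof=1) if len(g2) > 1 else None
    if v1 is None and v2 is None:
        raise ValueError("at least one group needs >= 2 models for a "
                         "dispersion estimate")
    if v1 is None or v2 is None:
        warnings.warn("a group has a single model; dispersion taken from "
                      "the other group")
        sigma = np.sqrt(v2 if v1 is None else v1)
    elif sigma_mode == "pooled":
        sigma = np.sqrt(((len(g1) - 1) * v1 + (len(g2) - 1) * v2)
                        / (len(g1) + len(g2) - 2))
    elif sigma_mode == "across_pairs":
        pair_diffs = np.stack([occ[a].to_numpy() - occ[b].to_numpy()
                               for a in g1 for b in g2], axis=1)
        sigma = pd.Series(pair_diffs.std(axis=1, ddof=1), index=occ.index)
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    selected = (diff.abs() > k * sigma) & (diff.abs() > absolute_floor)
    entries = pd.DataFrame({
        f"mean_{groups[0]}": m1, f"mean_{groups[1]}": m2,
        "difference": diff, "sigma": sigma, "selected": selected,
        "magnitude": diff.abs(),
    })
    return DifferenceMap(entries, (groups[0], groups[1]), k, absolute_floor)


def replicate_reproducibility(tables, stable_above: float = 0.90):
    """Per-bond mean occurrence and coefficient of variation across
    replicate runs, plus the fraction of bonds with mean occurrence above
    the stability cutoff.

    ``tables`` is an OccurrenceTable whose columns are replicates, or a list
    of single-model tables over the same system.
    """
    if isinstance(tables, OccurrenceTable):
        occ = tables.occurrence
    else:
        occ = pd.concat([t.occurrence.iloc[:, 0].rename(f"rep{i}")
                         for i, t in enumerate(tables)], axis=1).fillna(0.0)
    if occ.shape[1] < 2:
        raise ValueError("reproducibility needs at least 2 replicates")
    mean = occ.mean(axis=1)
    sd = occ.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    result = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
    result.loc[mean == 0, "cv"] = np.nan
    frac_stable = float((mean > stable_above).mean()) if len(mean) else 0.0
    return result, frac_stable


def compare_to_reference(table: OccurrenceTable, reference_bonds: list,
                         stability_cutoff: float = 0.90,
                         topology: Topology | None = None) -> dict:
    """Fraction of crystal-structure reference bonds recovered as stable
    (mean occurrence > cutoff), reported per bond class (e.g. Watson-Crick,
    main-chain, other).

    ``reference_bonds`` entries are (bond, class) where bond is an
    :class:`HBondKey` or a pair of ``chain:resnum:atom`` label strings
    (resolved against ``topology``).  Reference bonds that cannot be
    resolved to topology atoms are excluded with a warning and reported; a
    resolvable bond simply absent from the table counts as not recovered.
    """
    if not reference_bonds:
        raise ValueError("empty reference bond list")
    mean = table.occurrence.mean(axis=1)
    per_class: dict[str, list[bool]] = {}
    unresolved: list = []
    for bond, cls in reference_bonds:
        key = bond
        if not isinstance(bond, HBondKey):
            try:
                key = HBondKey(_resolve_label(topology, bond[0]),
                               _resolve_label(topology, bond[1]))
            except (KeyError, AttributeError, TypeError) as exc:
                unresolved.append((bond, str(exc)))
                continue
        occ = mean.get(key, mean.get(HBondKey(key.acceptor, key.donor), 0.0))
        per_class.setdefault(cls, []).append(occ > stability_cutoff)
    if unresolved:
        warnings.warn(f"{len(unresolved)} reference bonds could not be "
                      f"resolved in the topology and were excluded")
    return {
        "recovered_fraction": {cls: float(np.mean(v))
                               for cls, v in per_class.items()},
        "unresolved": unresolved,
    }


def _resolve_label(topology: Topology, label: str) -> int:
    chain, resnum, atom = label.split(":")
    return topology.atom_index(chain, int(resnum), atom)
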