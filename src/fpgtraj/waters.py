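"""Water-mediated bridges at the protein-DNA interface.

A bridge exists in a snapshot when one water molecule is simultaneously
hydrogen-bonded (same criterion as the bond-occurrence analysis) to two
(pair) or three (triplet) non-water donors/acceptors.  A water bonded to k
partners contributes all C(k,2) pairs and C(k,3) triplets; a partner set is
counted once per snapshot regardless of how many waters bridge it, with the
multiplicity kept in a separate histogram (a stably two-water-bridged pair,
like the carboxylate/O8-of-the-lesion site, is a phenomenon of its own).

Chemically equivalent partner atoms are merged by default (Glu OE1/OE2 and
Asp OD1/OD2 collapse to one carboxylate partner; phosphate O1P/O2P merging
is optional), matching how bridge partners are reported in the structural
literature.  Retention thresholds follow the lowest-quartile rule: keep the
bridges that collectively account for >75% of all occurrences, which for a
5000-snapshot run corresponds to fixed counts of 2000 (pairs) and 1500
(triplets).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import templates as T
from .hbonds import HBondParams, detect_hbonds
from .topology import Topology, Trajectory

#: default equivalent-atom merge groups (suffix '*' marks a merged label)
CARBOXYLATE_MERGES = {
    ("GLU", "OE1"): "OE*", ("GLU", "OE2"): "OE*",
    ("GLH", "OE1"): "OE*", ("GLH", "OE2"): "OE*",
    ("ASP", "OD1"): "OD*", ("ASP", "OD2"): "OD*",
}
PHOSPHATE_MERGES = {
    (None, "OP1"): "OP*", (None, "OP2"): "OP*",
    (None, "O1P"): "OP*", (None, "O2P"): "OP*",
}


@dataclass
class BridgeParams:
    hbond: HBondParams = field(default_factory=HBondParams)
    merge_carboxylates: bool = True
    merge_phosphates: bool = False


def partner_label(topology: Topology, atom: int,
                  params: BridgeParams | None = None) -> tuple:
    """Canonical (chain, resnum, resname, atom-or-merged) partner label."""
    p = params or BridgeParams()
    ri = topology.residue_index[atom]
    res = topology.residues[ri]
    aname = str(topology.names[atom])
    if p.merge_carboxylates:
        merged = CARBOXYLATE_MERGES.get((res.name.upper(), aname))
        if merged:
            aname = merged
    if p.merge_phosphates and (None, aname) in PHOSPHATE_MERGES:
        aname = PHOSPHATE_MERGES[(None, aname)]
    return (res.chain_id, res.number, res.name, aname)


def detect_bridges(snapshot: np.ndarray, topology: Topology,
                   params: BridgeParams | None = None):
    """Per-water bonded partner sets for one snapshot.

    Returns (water_partners, pair_waters, triplet_waters) where
    water_partners maps water residue index -> set of partner labels, and
    pair/triplet_waters map each emitted partner set (frozenset of labels)
    to the number of distinct waters bridging it in this snapshot.
    """
    p = params or BridgeParams()
    bonds = detect_hbonds(snapshot, topology, p.hbond)
    water_partners: dict[int, set] = defaultdict(set)
    atom_class = topology.atom_classes
    for key in bonds:
        d_water = atom_class[key.donor] == T.WATER
        a_water = atom_class[key.acceptor] == T.WATER
        if d_water == a_water:
            continue  # water-water and non-water bonds are not bridges
        water_atom = key.donor if d_water else key.acceptor
        partner_atom = key.acceptor if d_water else key.donor
        wri = int(topology.residue_index[water_atom])
        water_partners[wri].add(partner_label(topology, partner_atom, p))
    pair_waters: Counter = Counter()
    triplet_waters: Counter = Counter()
    for wri, partners in water_partners.items():
        if len(partners) < 2:
            continue
        for pair in combinations(sorted(partners), 2):
            pair_waters[frozenset(pair)] += 1
        for trip in combinations(sorted(partners), 3):
            triplet_waters[frozenset(trip)] += 1
    return dict(water_partners), pair_waters, triplet_waters


@dataclass
class BridgeCensus:
    """Occurrence counts of pair and triplet bridges over a trajectory."""

    records: pd.DataFrame       # partner_set, kind, count, n_waters histogram
    n_snapshots: int
    thresholds: dict = field(default_factory=dict)
    retained: pd.DataFrame | None = None

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.records[self.records["kind"] == kind]

    def rank_table(self, kind: str) -> pd.DataFrame:
        """Count-vs-rank table (descending) for rank plots."""
        sub = self.of_kind(kind).sort_values("count", ascending=False)
        sub = sub.reset_index(drop=True)
        sub.index.name = "rank"
        return sub


def bridge_census(traj: Trajectory, existence_floor: float = 0.0,
                  params: BridgeParams | None = None) -> BridgeCensus:
    """Census all water bridges over a trajectory (unthresholded).

    ``existence_floor`` drops partner sets seen in at most that fraction of
    snapshots.  Counts are invariant to snapshot order and water numbering.
    """
    p = params or BridgeParams()
    pair_counts: Counter = Counter()
    triplet_counts: Counter = Counter()
    multiplicity: dict[frozenset, Counter] = defaultdict(Counter)
    for si in range(traj.n_snapshots):
        _, pairs, triplets = detect_bridges(traj.coords[si], traj.topology, p)
        for ps, nw in pairs.items():
            pair_counts[ps] += 1
            multiplicity[ps][nw] += 1
        for ts, nw in triplets.items():
            triplet_counts[ts] += 1
            multiplicity[ts][nw] += 1
    rows = []
    for counts, kind in ((pair_counts, "pair"), (triplet_counts, "triplet")):
        for ps, c in counts.items():
            if c <= existence_floor * traj.n_snapshots:
                continue
            rows.append({
                "partner_set": tuple(sorted(ps)),
                "kind": kind,
                "count": c,
                "fraction": c / traj.n_snapshots,
                "n_waters_histogram": dict(sorted(multiplicity[ps].items())),
            })
    records = pd.DataFrame(
        rows, columns=["partner_set", "kind", "count", "fraction",
                       "n_waters_histogram"])
    records = records.sort_values(["kind", "count"],
                                  ascending=[True, False]).reset_index(drop=True)
    return BridgeCensus(records, traj.n_snapshots)


def apply_thresholds(census: BridgeCensus, mode: str = "fixed",
                     pair_count: float = 2000.0, triplet_count: float = 1500.0,
                     reference_length: int = 5000,
                     cumulative_share: float = 0.75) -> pd.DataFrame:
    """Retain high-occurrence bridges.

    mode "fixed": counts strictly above 2000 (pairs) / 1500 (triplets),
    rescaled proportionally when the trajectory length differs from the
    5000-snapshot reference.  mode "quantile": per kind, the smallest count
    cutoff whose retained records account for more than ``cumulative_share``
    of all occurrences (a level set: ties at the cutoff are kept together).
    """
    if census.records.empty:
        census.retained = census.records.copy()
        census.thresholds = {"mode": mode}
        return census.retained
    keep = np.zeros(len(census.records), dtype=bool)
    thresholds: dict = {"mode": mode}
    for kind, fixed in (("pair", pair_count), ("triplet", triplet_count)):
        sub = census.records["kind"] == kind
        counts = census.records.loc[sub, "count"].to_numpy()
        if counts.size == 0:
            continue
        if mode == "fixed":
            cut = fixed * census.n_snapshots / reference_length
            keep[sub.to_numpy()] = counts > cut
            thresholds[kind] = cut
        elif mode == "quantile":
            order = np.argsort(-counts)
            csum = np.cumsum(counts[order])
            total = csum[-1]
            first = int(np.argmax(csum > cumulative_share * total))
            cut_level = counts[order][first]
            keep[sub.to_numpy()] = counts >= cut_level
            thresholds[kind] = cut_level
        else:
            raise ValueError(f"unknown threshold mode {mode!r}")
    census.thresholds = thresholds
    census.retained = census.records[keep].reset_index(drop=True)
    return census.retained


def multi_water_bridges(traj: Trajectory, partner_pair, min_waters: int = 2,
                        params: BridgeParams | None = None):
    """Snapshot-by-snapshot count of distinct waters simultaneously bonded
    to both partners of a fixed pair.

    ``partner_pair`` is a pair of partner labels (as from
    :func:`partner_label`) or atom indices.  Returns (counts, indicator,
    occurrence) where indicator is True when >= min_waters waters bridge
    the pair and occurrence is the number of such snapshots.
    """
    p = params or BridgeParams()
    labels = []
    for item in partner_pair:
        if isinstance(item, (int, np.integer)):
            labels.append(partner_label(traj.topology, int(item), p))
        else:
            labels.append(tuple(item))
    target = frozenset(labels)
    if len(target) != 2:
        raise ValueError("partner pair must name two distinct partners")
    counts = np.zeros(traj.n_snapshots, dtype=int)
    for si in range(traj.n_snapshots):
        water_partners, _, _ = detect_bridges(traj.coords[si], traj.topology, p)
        counts[si] = sum(1 for partners in water_partners.values()
                         if target <= partners)
    indicator = counts >= min_waters
    return counts, indicator, int(indicator.sum())
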