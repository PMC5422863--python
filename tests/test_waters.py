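"""Water-bridge detection, censusing and retention thresholds."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import fpgtraj as F
from fpgtraj.waters import BridgeParams, partner_label


def test_pair_and_triplet_combinatorics(toy, short_run):
    """A water bonded to k partners emits C(k,2) pairs and C(k,3) triplets."""
    traj, man = short_run
    # the 3-partner station: find a snapshot where its bridge is on
    si = int(np.flatnonzero(man.bridge_states[1])[0])
    water_partners, pairs, triplets = F.detect_bridges(traj.coords[si],
                                                       toy.topology)
    st = toy.bridge_stations[1]
    wri = int(toy.topology.residue_index[st.water_atoms[0][0]])
    partners = water_partners[wri]
    assert len(partners) == 3
    for pair in combinations(sorted(partners), 2):
        assert pairs[frozenset(pair)] >= 1
    assert triplets[frozenset(partners)] >= 1
    # 2-partner station: one pair, no triplet
    si = int(np.flatnonzero(man.bridge_states[0])[0])
    water_partners, pairs, triplets = F.detect_bridges(traj.coords[si],
                                                       toy.topology)
    st0 = toy.bridge_stations[0]
    wri0 = int(toy.topology.residue_index[st0.water_atoms[0][0]])
    assert len(water_partners[wri0]) == 2
    assert frozenset(water_partners[wri0]) in pairs
    assert not any(frozenset(water_partners[wri0]) <= t for t in triplets)


def test_detect_bridges_equals_brute_force(toy, rng):
    """Emissions equal brute-force enumeration over waters x subsets."""
    from fpgtraj import detect_hbonds
    import fpgtraj.templates as T

    p = BridgeParams()
    for trial in range(5):
        snap = toy.coords + rng.normal(0, 0.5, toy.coords.shape)
        got_partners, got_pairs, got_triplets = F.detect_bridges(
            snap, toy.topology, p)
        bonds = detect_hbonds(snap, toy.topology, p.hbond)
        cls = toy.topology.atom_classes
        partners = {}
        for k in bonds:
            dw = cls[k.donor] == T.WATER
            aw = cls[k.acceptor] == T.WATER
            if dw == aw:
                continue
            w = k.donor if dw else k.acceptor
            other = k.acceptor if dw else k.donor
            wri = int(toy.topology.residue_index[w])
            partners.setdefault(wri, set()).add(
                partner_label(toy.topology, other, p))
        pairs, triplets = {}, {}
        for wri, ps in partners.items():
            for c in combinations(sorted(ps), 2):
                pairs[frozenset(c)] = pairs.get(frozenset(c), 0) + 1
            for c in combinations(sorted(ps), 3):
                triplets[frozenset(c)] = triplets.get(frozenset(c), 0) + 1
        assert {k: v for k, v in got_pairs.items()} == pairs
        assert {k: v for k, v in got_triplets.items()} == triplets


def test_census_recovers_planted_counts(toy, short_run):
    traj, man = short_run
    census = F.bridge_census(traj)
    counts = {(tuple(r["partner_set"]), r["kind"]): r["count"]
              for _, r in census.records.iterrows()}
    for ps, kind, c in zip(man.bridge_partner_sets, man.bridge_kinds,
                           man.bridge_counts):
        assert counts[(ps, kind)] == c  # noiseless: exact
    assert census.n_snapshots == traj.n_snapshots


def test_census_invariant_to_snapshot_order(toy, short_run):
    traj, _ = short_run
    sub = F.Trajectory(toy.topology, traj.coords[:60])
    shuffled = F.Trajectory(toy.topology, traj.coords[:60][::-1].copy())
    c1 = F.bridge_census(sub).records
    c2 = F.bridge_census(shuffled).records
    k1 = sorted((tuple(r["partner_set"]), r["kind"], r["count"])
                for _, r in c1.iterrows())
    k2 = sorted((tuple(r["partner_set"]), r["kind"], r["count"])
                for _, r in c2.iterrows())
    assert k1 == k2


def test_multiplicity_histogram_for_double_water_bridge(toy, short_run):
    """The two-water station counts its snapshot once, multiplicity 2."""
    traj, man = short_run
    census = F.bridge_census(traj)
    row = census.records[
        census.records["partner_set"].apply(tuple) == man.bridge_partner_sets[2]]
    hist = row.iloc[0]["n_waters_histogram"]
    assert set(hist) == {2}
    assert hist[2] == man.bridge_counts[2]


def test_multi_water_bridge_indicator(toy, short_run):
    traj, man = short_run
    pair = man.bridge_partner_sets[2]
    counts, indicator, occ = F.multi_water_bridges(traj, pair, min_waters=2)
    assert occ == man.bridge_counts[2]
    # with min_waters=1 occurrence can only grow
    _, _, occ1 = F.multi_water_bridges(traj, pair, min_waters=1)
    assert occ1 >= occ
    # a single-water pair never reaches min_waters=2
    single = man.bridge_partner_sets[0]
    _, _, occ2 = F.multi_water_bridges(traj, single, min_waters=2)
    assert occ2 == 0


def _census_from_counts(pair_counts, triplet_counts=(), n=5000):
    rows = []
    for i, c in enumerate(pair_counts):
        rows.append({"partner_set": (("A", i, "GLY", "O"), ("A", 100 + i, "GLY", "O")),
                     "kind": "pair", "count": c, "fraction": c / n,
                     "n_waters_histogram": {1: c}})
    for i, c in enumerate(triplet_counts):
        rows.append({"partner_set": (("B", i, "GLY", "O"), ("B", 50 + i, "GLY", "O"),
                                     ("B", 90 + i, "SER", "OG")),
                     "kind": "triplet", "count": c, "fraction": c / n,
                     "n_waters_histogram": {1: c}})
    return F.BridgeCensus(pd.DataFrame(rows), n)


def test_fixed_thresholds_and_length_rescaling():
    census = _census_from_counts([2100, 1900], [1600, 1400])
    kept = F.apply_thresholds(census, mode="fixed")
    pairs = kept[kept["kind"] == "pair"]["count"].tolist()
    trips = kept[kept["kind"] == "triplet"]["count"].tolist()
    assert pairs == [2100] and trips == [1600]
    # half-length trajectory: thresholds scale to 1000/750
    census = _census_from_counts([1100, 900], [800, 700], n=2500)
    kept = F.apply_thresholds(census, mode="fixed")
    assert kept[kept["kind"] == "pair"]["count"].tolist() == [1100]
    assert kept[kept["kind"] == "triplet"]["count"].tolist() == [800]


def test_quantile_threshold_uniform_keeps_all():
    census = _census_from_counts([500] * 8)
    kept = F.apply_thresholds(census, mode="quantile")
    assert len(kept) == 8


def test_quantile_threshold_cumulative_sum_oracle():
    counts = [4000, 3000, 2000] + [500] * 10
    census = _census_from_counts(counts)
    kept = F.apply_thresholds(census, mode="quantile")
    got = sorted(kept["count"].tolist(), reverse=True)
    # independent cumulative-sum evaluation
    total = sum(counts)
    s = sorted(counts, reverse=True)
    acc, expect = 0, []
    for c in s:
        if acc > 0.75 * total and c < expect[-1]:
            break
        expect.append(c)
        acc += c
        if acc > 0.75 * total:
            # keep ties at the cutoff level
            cutoff = c
            expect.extend(x for x in s[len(expect):] if x == cutoff)
            break
    assert got == expect
    assert sum(got) > 0.75 * total
    # level-set property: every retained count >= every dropped count
    dropped = census.records[~census.records.index.isin(kept.index)]
    if len(dropped) and len(kept):
        assert kept["count"].min() >= dropped["count"].max()


def test_census_invariant_to_water_renumbering(toy, short_run):
    traj, _ = short_run
    sub_coords = traj.coords[:40].copy()
    c1 = F.bridge_census(F.Trajectory(toy.topology, sub_coords)).records
    # renumber waters by rebuilding the topology with shifted water resnums
    from fpgtraj.topology import AtomRecord, Topology, classify_residues
    recs = []
    for i in range(toy.topology.n_atoms):
        ri = toy.topology.residue_index[i]
        res = toy.topology.residues[ri]
        num = res.number + 1000 if res.res_class == "water" else res.number
        recs.append(AtomRecord(i + 1, toy.topology.names[i],
                               toy.topology.elements[i], "", res.name, num,
                               res.chain_id, toy.coords[i]))
    top2 = Topology(recs)
    classify_residues(top2, coords=toy.coords)
    c2 = F.bridge_census(F.Trajectory(top2, sub_coords)).records
    k1 = sorted((r["kind"], r["count"]) for _, r in c1.iterrows())
    k2 = sorted((r["kind"], r["count"]) for _, r in c2.iterrows())
    assert k1 == k2


def test_no_waters_gives_empty_census(toy):
    # strip waters by selecting the protein+DNA subsystem
    from fpgtraj.topology import AtomRecord, Topology, classify_residues
    keep = [i for i in range(toy.topology.n_atoms)
            if toy.topology.atom_classes[i] != "water"]
    recs = [AtomRecord(j + 1, toy.topology.names[i], toy.topology.elements[i],
                       "", toy.topology.res_names[i],
                       int(toy.topology.res_numbers[i]),
                       toy.topology.chain_ids[i], toy.coords[i])
            for j, i in enumerate(keep)]
    top = Topology(recs)
    classify_residues(top, coords=toy.coords[keep])
    census = F.bridge_census(F.Trajectory(top, toy.coords[keep][None]))
    assert census.records.empty
    assert F.apply_thresholds(census).empty


def test_carboxylate_merging_collapses_oe_atoms(toy):
    top = toy.topology
    glu = top.find_residue("A", 2)
    oe1 = top.atom_in_residue(glu, "OE1")
    oe2 = top.atom_in_residue(glu, "OE2")
    assert partner_label(top, oe1) == partner_label(top, oe2)
    p = BridgeParams(merge_carboxylates=False)
    assert partner_label(top, oe1, p) != partner_label(top, oe2, p)
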