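"""Hydrogen-bond energy, detection and occurrence statistics."""

import numpy as np
import pandas as pd
import pytest

import fpgtraj as F
from fpgtraj.hbonds import HBondKey, HBondParams, OccurrenceTable


def test_energy_anchor_and_decay():
    d = np.zeros(3)
    h = np.array([0.97, 0, 0])
    # optimum: 2.9 Angstrom, linear -> the full well depth of 2.8 kcal/mol
    assert F.hbond_energy(d, h, np.array([2.9, 0, 0])) == pytest.approx(2.8)
    assert F.hbond_energy(d, h, np.array([6.0, 0, 0])) < 0.1
    # short-range repulsion clamps to zero
    assert F.hbond_energy(d, h, np.array([2.2, 0, 0])) == 0.0
    # reversed hydrogen (pointing away) scores zero
    assert F.hbond_energy(d, np.array([-0.97, 0, 0]),
                          np.array([2.9, 0, 0])) == 0.0


def test_energy_profile_matches_closed_form_grid():
    eps, sig = 2.8, 2.9
    dist = np.linspace(2.0, 6.0, 100)
    got = np.array([F.hbond_energy(np.zeros(3), np.array([0.97, 0, 0]),
                                   np.array([x, 0, 0])) for x in dist])
    x = sig / dist
    expect = np.maximum(-eps * (5 * x ** 12 - 6 * x ** 10), 0.0)
    assert np.allclose(got, expect, atol=1e-10)


def test_energy_angular_weight():
    d = np.zeros(3)
    a = np.array([2.9, 0, 0])
    for theta in (10.0, 30.0, 60.0):
        h = 0.97 * np.array([np.cos(np.radians(theta)),
                             np.sin(np.radians(theta)), 0.0])
        # D-H...A deviation from linear is not simply theta; compute directly
        got = F.hbond_energy(d, h, a)
        u = d - h
        v = a - h
        dev = 180.0 - np.degrees(np.arccos(
            u @ v / np.linalg.norm(u) / np.linalg.norm(v)))
        expect = 2.8 * np.cos(np.radians(dev)) ** 4 if dev < 90 else 0.0
        assert got == pytest.approx(expect, abs=1e-9)


def test_detect_ideal_and_out_of_range(toy):
    # planted station 0: donor OG..HG1 -> acceptor OG at the on-distance
    st = toy.hbond_stations[0]
    hits = F.detect_hbonds(toy.coords, toy.topology)
    assert HBondKey(st.donor, st.acceptor) in hits
    moved = toy.coords.copy()
    moved[st.acceptor_atoms] += np.array([2.95, 0.0, 0.0])  # -> 6.0 A
    hits = F.detect_hbonds(moved, toy.topology)
    assert HBondKey(st.donor, st.acceptor) not in hits


def test_detect_equals_brute_force_all_pairs(toy, rng):
    """KD-tree accelerated detection is exactly all-pairs evaluation."""
    from fpgtraj.hbonds import _pair_score
    p = HBondParams()
    for trial in range(8):
        snap = toy.coords + rng.normal(0, 1.0, toy.coords.shape)
        got = F.detect_hbonds(snap, toy.topology, p)
        brute = set()
        for dn in toy.topology.donors:
            for ai in toy.topology.acceptors:
                ai = int(ai)
                if ai == dn.heavy:
                    continue
                if toy.topology.residue_index[ai] == \
                        toy.topology.residue_index[dn.heavy]:
                    continue
                score = _pair_score(snap, toy.topology, dn, ai, p)
                if score is not None and score > p.threshold:
                    brute.add(HBondKey(dn.heavy, ai))
        assert got == brute


def test_geometric_fallback_agrees_on_planted_states(toy):
    """The distance/angle fallback criterion matches the energy criterion
    on ideal and broken planted bonds (>= 90% agreement required; here the
    geometry is clean so agreement is exact)."""
    geo = HBondParams(criterion="geometric")
    st = toy.hbond_stations[1]
    key = HBondKey(st.donor, st.acceptor)
    assert key in F.detect_hbonds(toy.coords, toy.topology, geo)
    moved = toy.coords.copy()
    moved[st.acceptor_atoms] += np.array([2.95, 0.0, 0.0])
    assert key not in F.detect_hbonds(moved, toy.topology, geo)


def test_occurrence_table_planted_and_floor(toy):
    plan = F.PlantSpec(hbonds=[F.HBondPlant(1.0), F.HBondPlant(0.4),
                               F.HBondPlant(0.005)],
                       noise_sigma=0.0, seed=7)
    traj, man = F.simulate_trajectory(toy, plan, 500)
    tab = F.occurrence_table({"m": traj})
    occ = tab.occurrence["m"]
    assert occ[man.hbond_keys[0]] == 1.0
    got = occ[man.hbond_keys[1]]
    assert got == man.hbond_occurrences[1]
    sig3 = 3 * np.sqrt(0.4 * 0.6 / 500)
    # Markov-correlated realization; detector agrees exactly with realized
    assert abs(got - man.hbond_occurrences[1]) <= sig3
    # a bond below the 1% floor in every model is absent
    if man.hbond_occurrences[2] <= 0.01:
        assert man.hbond_keys[2] not in occ.index


def test_occurrence_table_bernoulli_recovery(toy, rng):
    """i.i.d. plant at p=0.4 recovered within binomial 3 sigma of p."""
    plan = F.PlantSpec(hbonds=[F.HBondPlant(0.4, correlation_time=1.0)],
                       noise_sigma=0.05, seed=19)
    traj, man = F.simulate_trajectory(toy, plan, 1500)
    tab = F.occurrence_table({"m": traj})
    got = tab.occurrence["m"][man.hbond_keys[0]]
    assert abs(got - 0.4) <= 3 * np.sqrt(0.4 * 0.6 / 1500)


def test_classify_stability_partition():
    occ = pd.Series({1: 0.95, 2: 0.25, 3: 0.50, 4: 0.901, 5: 0.0})
    got = F.classify_stability(occ)
    assert got[1] == "stable"
    assert got[2] == "fluctuating"      # boundary inclusive
    assert got[3] == "intermediate"
    assert got[4] == "stable"
    assert got[5] == "fluctuating"
    assert F.classify_stability(0.95) == "stable"
    # partition: every value lands in exactly one class
    vals = pd.Series(np.linspace(0, 1, 101))
    cats = F.classify_stability(vals)
    assert set(cats.unique()) <= {"stable", "intermediate", "fluctuating"}


def test_phi_coefficient_identity_formula_and_independence(rng):
    idx = pd.RangeIndex(80)
    a = pd.Series(np.where(np.arange(80) < 40, 0.95, 0.1), index=idx)
    phi, table, flag = F.phi_coefficient(a, a)
    assert phi == 1.0 and not flag
    # direct formula case (a,b,c,d) = (30,10,10,30) -> 0.5
    ca = np.array([True] * 40 + [False] * 40)
    cb = np.concatenate([[True] * 30 + [False] * 10, [True] * 10 + [False] * 30])
    sa = pd.Series(np.where(ca, 0.95, 0.1))
    sb = pd.Series(np.where(cb, 0.95, 0.1))
    phi, table, flag = F.phi_coefficient(sa, sb)
    assert (table == np.array([[30, 10], [10, 30]])).all()
    assert phi == pytest.approx(0.5)
    # independent categories -> |phi| < 0.03 at n = 10^4
    n = 10_000
    sa = pd.Series(np.where(rng.random(n) < 0.5, 0.95, 0.1))
    sb = pd.Series(np.where(rng.random(n) < 0.5, 0.95, 0.1))
    phi, _, _ = F.phi_coefficient(sa, sb)
    assert abs(phi) < 0.03


def test_phi_degenerate_margin_flagged():
    a = pd.Series([0.95, 0.95])
    b = pd.Series([0.95, 0.1])
    phi, _, flag = F.phi_coefficient(a, b)
    assert phi == 0.0 and flag
    with pytest.raises(ValueError):
        F.phi_coefficient(pd.Series(dtype=float), pd.Series(dtype=float))


def _table_from_dict(data):
    df = pd.DataFrame(data)
    return OccurrenceTable(df, {c: 5000 for c in df.columns})


def test_group_specific_bonds_planted_selection():
    data = {
        "C1": [0.92, 0.5], "C2": [0.95, 0.52], "C3": [0.90, 0.49],
        "C4": [0.93, 0.51],
        "A1": [0.10, 0.5], "A2": [0.15, 0.52], "A3": [0.12, 0.48],
        "A4": [0.08, 0.50],
    }
    tab = _table_from_dict(data)
    grouping = {m: m[0] for m in data}
    dm = F.group_specific_bonds(tab, grouping)
    assert dm.entries["selected"].tolist() == [True, False]
    # identical occurrences everywhere -> nothing selected
    flat = _table_from_dict({m: [0.5, 0.7] for m in data})
    dm = F.group_specific_bonds(flat, grouping)
    assert not dm.entries["selected"].any()


def test_group_specific_rejects_wide_within_group_spread():
    # delta = 0.2 but within-group spread ~0.3 -> not selected
    data = {"C1": [0.2], "C2": [0.8], "C3": [0.5],
            "A1": [0.1], "A2": [0.4], "A3": [0.4]}
    tab = _table_from_dict(data)
    dm = F.group_specific_bonds(tab, {m: m[0] for m in data})
    assert not dm.entries["selected"].any()


def test_group_specific_monotone_in_k():
    rng = np.random.default_rng(3)
    data = {f"{g}{i}": rng.random(50) * (0.9 if g == "C" else 0.4)
            for g in "CA" for i in range(4)}
    tab = _table_from_dict({k: list(v) for k, v in data.items()})
    grouping = {m: m[0] for m in data}
    prev = None
    for k in (0.0, 1.0, 3.0, 10.0, 1e9):
        sel = F.group_specific_bonds(tab, grouping, k=k,
                                     absolute_floor=0.0).entries["selected"]
        if prev is not None:
            assert set(sel[sel].index) <= set(prev[prev].index)
        prev = sel
    assert not prev.any()  # k -> infinity selects nothing
    sel0 = F.group_specific_bonds(tab, grouping, k=0.0,
                                  absolute_floor=0.0).entries
    nonzero = sel0["difference"].abs() > 0
    assert sel0.loc[nonzero, "selected"].all()


def test_replicate_reproducibility_cv():
    idx = ["b1", "b2", "b3"]
    occ = pd.DataFrame({
        "r1": [1.0, 0.5, 0.0], "r2": [1.0, 0.5, 0.0],
        "r3": [1.0, 0.5, 0.0], "r4": [0.0, 0.5, 0.0]}, index=idx)
    tab = OccurrenceTable(occ, {c: 5000 for c in occ})
    res, frac = F.replicate_reproducibility(tab)
    # identical replicates -> cv 0
    assert res.loc["b2", "cv"] == 0.0
    # one absent replicate out of four at occurrence 1.0: direct computation
    vals = np.array([1.0, 1.0, 1.0, 0.0])
    expect = vals.std(ddof=1) / vals.mean()
    assert res.loc["b1", "cv"] == pytest.approx(expect)
    assert np.isnan(res.loc["b3", "cv"])
    assert frac == pytest.approx(0.0)


def test_replicate_reproducibility_binomial_scaling(toy):
    """Planted p=0.5 i.i.d. bonds: CV across replicates ~ sqrt((1-p)/(p n))."""
    plan = lambda seed: F.PlantSpec(
        hbonds=[F.HBondPlant(0.5, correlation_time=1.0)],
        noise_sigma=0.0, seed=seed)
    tables = []
    for seed in (101, 102, 103, 104):
        traj, _ = F.simulate_trajectory(toy, plan(seed), 1200)
        tables.append(F.occurrence_table({f"r{seed}": traj}))
    occ = pd.concat([t.occurrence.iloc[:, 0] for t in tables], axis=1).fillna(0)
    key = F.HBondKey(toy.hbond_stations[0].donor, toy.hbond_stations[0].acceptor)
    res, _ = F.replicate_reproducibility(
        OccurrenceTable(occ, {c: 1200 for c in occ}))
    expect = np.sqrt(0.5 / (0.5 * 1200))
    # CV estimated from 4 replicates is noisy; 3-sigma-ish envelope
    assert res.loc[key, "cv"] < 4 * expect
    assert res.loc[key, "mean"] == pytest.approx(0.5, abs=0.05)


def test_compare_to_reference_recovery(toy):
    plan = F.PlantSpec(hbonds=[F.HBondPlant(0.98), F.HBondPlant(0.98),
                               F.HBondPlant(0.5)], noise_sigma=0.0, seed=23)
    traj, man = F.simulate_trajectory(toy, plan, 600)
    tab = F.occurrence_table({"m": traj})
    ref = [(man.hbond_keys[0], "watson-crick"),
           (man.hbond_keys[1], "main-chain"),
           (man.hbond_keys[2], "main-chain")]
    out = F.compare_to_reference(tab, ref)
    assert out["recovered_fraction"]["watson-crick"] == 1.0
    assert out["recovered_fraction"]["main-chain"] == 0.5
    with pytest.raises(ValueError):
        F.compare_to_reference(tab, [])
    with pytest.warns(UserWarning, match="resolved"):
        out = F.compare_to_reference(
            tab, ref + [(("Q:999:XX", "Q:998:YY"), "other")],
            topology=toy.topology)
    assert len(out["unresolved"]) == 1
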