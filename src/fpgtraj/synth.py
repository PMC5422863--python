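"""Synthetic protein-DNA-water complexes and trajectories with planted truth.

The generator emulates the study conditions of a glycosylase pre-catalytic
complex trajectory — a kinked 14-bp duplex with a central 8-oxoguanine
lesion (base-pair labels -7..+6, lesion at 0), a small protein scaffold
with a Pro1/Glu2-like catalytic dyad and Arg/Phe stand-ins, explicit
waters, and a 2 ps snapshot cadence — while keeping every downstream
observable under exact control:

* hydrogen-bond plants: isolated donor/acceptor stations toggled between
  a near-ideal linear on-state (3.05 Angstrom) and a broken state
  (6.0 Angstrom) by a
  two-state Markov chain with a chosen stationary occurrence and
  correlation time (default 10 snapshots — trajectory occupancy series
  have visible persistence, so i.i.d. toggling would be unrealistic);
* water-bridge plants: 2- or 3-partner stations whose bridging water(s)
  jump between the trigonometrically solved bridging position and a remote
  parking site;
* a glycosidic-angle process: the lesion base rotates about the C1'-N9
  bond through a finite-state Markov chain over chi values;
* a catalytic-geometry plant: the Pro1 stand-in shuttles between an
  optimal attack arrangement (d1 = 3.5 A, d2 = 4.0 A, 107/180 degree
  angles) and a d1-violating arrangement;
* isotropic Gaussian coordinate noise added last.

Everything is reproducible from the seed, and the emitted
:class:`TruthManifest` records the realized state of every plant in every
snapshot.  The toy protein is a geometric scaffold, not a folded domain —
sufficient because all downstream analyses are geometry- and
topology-driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hbonds import HBondKey
from .topology import AtomRecord, Topology, Trajectory, classify_residues

RISE = 3.38      # Angstrom per base pair
TWIST = 36.0     # degrees per base pair
GLYCO_RADIUS = 5.2
WC_GAP = 2.9     # target closest-approach of the paired bases' WC edges
# planted bonds sit slightly outside the 10-12 well optimum (2.9 A): the
# repulsive wall is only ~0.25 A inside the optimum, so centering the
# on-state in the detection window keeps recovery robust to coordinate noise
HB_ON = 3.05     # Angstrom, planted on-state donor-acceptor distance
HB_OFF = 6.0     # Angstrom, planted broken-state distance

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _unit(v):
    return v / np.linalg.norm(v)


def _rot(axis, deg):
    axis = _unit(np.asarray(axis, dtype=float))
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


# ---------------------------------------------------------------------------
# 2-D base and sugar templates (regular fused polygons; chemically plausible
# bond lengths, not crystallographic geometry)

def _polygon(n, side, start_angle=0.0):
    r = side / (2.0 * np.sin(np.pi / n))
    ang = start_angle + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def _purine_2d(kind: str) -> dict[str, np.ndarray]:
    """2-D purine template; kind in {"A", "G", "8OG"}."""
    pent = _polygon(5, 1.38)
    atoms = dict(zip(("N9", "C8", "N7", "C5", "C4"), pent))
    c4, c5 = atoms["C4"], atoms["C5"]
    mid = (c4 + c5) / 2.0
    out = _unit(mid - pent.mean(0))
    hex_center = mid + out * (1.38 * np.sqrt(3) / 2.0)
    # walk the hexagon from C5 around to C4
    v = atoms["C5"] - hex_center
    step = _rot(_Z, 60.0)[:2, :2]
    names = ("C6", "N1", "C2", "N3")
    walk = v.copy()
    seq = []
    for _ in range(4):
        walk = step @ walk
        seq.append(hex_center + walk)
    if np.linalg.norm((step @ walk) + hex_center - atoms["C4"]) > 1e-6:
        step = _rot(_Z, -60.0)[:2, :2]
        walk = v.copy()
        seq = []
        for _ in range(4):
            walk = step @ walk
            seq.append(hex_center + walk)
    atoms.update(zip(names, seq))

    def _exo(base, center, length):
        return atoms[base] + length * _unit(atoms[base] - center)

    pent_center = pent.mean(0)
    if kind in ("G", "8OG"):
        atoms["O6"] = _exo("C6", hex_center, 1.23)
        atoms["N2"] = _exo("C2", hex_center, 1.34)
        n2dir = _unit(atoms["N2"] - atoms["C2"])
        atoms["H21"] = atoms["N2"] + (_rot(_Z, 25.0)[:2, :2] @ n2dir)
        atoms["H22"] = atoms["N2"] + (_rot(_Z, -25.0)[:2, :2] @ n2dir)
        atoms["H1"] = _exo("N1", hex_center, 1.00)
    else:  # adenine
        atoms["N6"] = _exo("C6", hex_center, 1.34)
        n6dir = _unit(atoms["N6"] - atoms["C6"])
        atoms["H61"] = atoms["N6"] + (_rot(_Z, 25.0)[:2, :2] @ n6dir)
        atoms["H62"] = atoms["N6"] + (_rot(_Z, -25.0)[:2, :2] @ n6dir)
    if kind == "8OG":
        atoms["O8"] = _exo("C8", pent_center, 1.23)
        atoms["H7"] = _exo("N7", pent_center, 1.00)
    return atoms


def _pyrimidine_2d(kind: str) -> dict[str, np.ndarray]:
    """2-D pyrimidine template; kind in {"C", "T"}."""
    hexv = _polygon(6, 1.39)
    atoms = dict(zip(("N1", "C2", "N3", "C4", "C5", "C6"), hexv))
    center = hexv.mean(0)

    def _exo(base, length):
        return atoms[base] + length * _unit(atoms[base] - center)

    atoms["O2"] = _exo("C2", 1.23)
    if kind == "C":
        atoms["N4"] = _exo("C4", 1.34)
        n4dir = _unit(atoms["N4"] - atoms["C4"])
        atoms["H41"] = atoms["N4"] + (_rot(_Z, 25.0)[:2, :2] @ n4dir)
        atoms["H42"] = atoms["N4"] + (_rot(_Z, -25.0)[:2, :2] @ n4dir)
    else:
        atoms["O4"] = _exo("C4", 1.23)
        atoms["H3"] = _exo("N3", 1.00)
    return atoms


_BASE_2D = {"DA": ("A", _purine_2d), "DG": ("G", _purine_2d),
            "8OG": ("8OG", _purine_2d),
            "DC": ("C", _pyrimidine_2d), "DT": ("T", _pyrimidine_2d)}

COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG"}

#: bonds asserted by the plausibility check (within each nucleotide)
NUCLEOTIDE_BONDS = [("C1'", "O4'"), ("O4'", "C4'"), ("C4'", "C3'"),
                    ("C3'", "C2'"), ("C2'", "C1'"), ("C4'", "C5'"),
                    ("C5'", "O5'"), ("O5'", "P"), ("P", "OP1"), ("P", "OP2"),
                    ("C3'", "O3'")]


def _base_atoms_3d(resname: str, glyco_pos, inward, normal):
    """Map a 2-D base template into 3-D: glycosidic N at ``glyco_pos``, base
    body extending along ``inward``, plane normal ``normal``."""
    kind, builder = _BASE_2D[resname]
    atoms2d = _purine_2d(kind) if builder is _purine_2d else _pyrimidine_2d(kind)
    anchor = "N9" if builder is _purine_2d else "N1"
    origin2d = atoms2d[anchor]
    # glycosidic attachment along the internal bisector of the two ring
    # bonds at the anchor nitrogen, so C1'(-x side) sees ~126 degree angles
    # to both ring neighbors instead of a near-collinear arrangement
    nb1, nb2 = ("C8", "C4") if anchor == "N9" else ("C2", "C6")
    xdir2d = _unit(_unit(atoms2d[nb1] - origin2d)
                   + _unit(atoms2d[nb2] - origin2d))
    ydir2d = np.array([-xdir2d[1], xdir2d[0]])
    u = _unit(np.asarray(inward, dtype=float))
    w = _unit(np.cross(normal, u))
    out = {}
    for name, p in atoms2d.items():
        rel = p - origin2d
        out[name] = (np.asarray(glyco_pos, dtype=float)
                     + (rel @ xdir2d) * u + (rel @ ydir2d) * w)
    return out, anchor


def _sugar_atoms_3d(glyco_pos, outward, axis):
    """Furanose ring (regular pentagon) plus backbone atoms.

    C1' sits 1.47 A outward of the glycosidic nitrogen; the ring lies in
    the (outward, axis) plane; the phosphate extends further outward.
    """
    u = _unit(np.asarray(outward, dtype=float))
    a = _unit(np.asarray(axis, dtype=float) - (axis @ u) * u)
    ring2d = _polygon(5, 1.47, start_angle=np.pi)  # C1' toward -x
    names = ("C1'", "O4'", "C4'", "C3'", "C2'")
    c1_2d = ring2d[0]
    c1 = glyco_pos + 1.47 * u
    center = c1 - (c1_2d[0]) * u - (c1_2d[1]) * a  # ring center in 3-D
    out = {}
    for name, p in zip(names, ring2d):
        out[name] = center + p[0] * u + p[1] * a
    side = _unit(np.cross(u, a))
    out["O3'"] = out["C3'"] + 1.43 * _unit(-a + 0.3 * u)
    out["C5'"] = out["C4'"] + 1.52 * _unit(a + 0.8 * u)
    out["O5'"] = out["C5'"] + 1.43 * _unit(a + 0.5 * u + 0.4 * side)
    p_pos = out["O5'"] + 1.60 * _unit(0.8 * u + 0.4 * a + 0.3 * side)
    out["P"] = p_pos
    out["OP1"] = p_pos + 1.48 * _unit(u + side)
    out["OP2"] = p_pos + 1.48 * _unit(u - side)
    return out


# ---------------------------------------------------------------------------
# plant specifications

@dataclass
class HBondPlant:
    occurrence: float
    correlation_time: float = 10.0   # snapshots


@dataclass
class BridgePlant:
    n_partners: int = 2     # 2 (pair) or 3 (triplet station)
    n_waters: int = 1       # waters simultaneously bridging when on
    occurrence: float = 0.8
    correlation_time: float = 10.0

    def __post_init__(self) -> None:
        if self.n_partners not in (2, 3):
            raise ValueError("bridge partner sets have size 2 or 3")
        if self.n_waters not in (1, 2):
            raise ValueError("1 or 2 bridging waters supported")


@dataclass
class ChiProcess:
    states: tuple[float, ...] = (-120.0, 60.0)   # anti and syn-ish, degrees
    stay_probability: float = 0.98               # per-snapshot


@dataclass
class CensusPlant:
    fraction: float = 0.2
    correlation_time: float = 10.0


@dataclass
class PlantSpec:
    """Full ground-truth plan for one synthetic trajectory."""

    hbonds: list[HBondPlant] = field(default_factory=list)
    bridges: list[BridgePlant] = field(default_factory=list)
    chi: ChiProcess | None = None
    census: CensusPlant | None = None
    noise_sigma: float = 0.05    # Angstrom, per coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.hbonds:
            if not 0.0 <= p.occurrence <= 1.0:
                raise ValueError("plant occurrence must be in [0, 1]")
        for p in self.bridges:
            if not 0.0 <= p.occurrence <= 1.0:
                raise ValueError("plant occurrence must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def parse_plan(text: str) -> PlantSpec:
    """Parse a plain-text plant plan.

    Example::

        hbond occurrence=0.4 tau=10
        bridge partners=3 waters=1 occurrence=0.8
        chi states=-120,60 stay=0.98
        census fraction=0.2
        noise 0.05
        seed 7
    """
    plan = PlantSpec()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kw = parts[0].lower()
        kv = {}
        for p in parts[1:]:
            if "=" in p:
                k, v = p.split("=", 1)
                kv[k] = v
            else:
                kv["_"] = p
        if kw == "hbond":
            plan.hbonds.append(HBondPlant(
                occurrence=float(kv.get("occurrence", kv.get("_", 0.5))),
                correlation_time=float(kv.get("tau", 10.0))))
        elif kw == "bridge":
            plan.bridges.append(BridgePlant(
                n_partners=int(kv.get("partners", 2)),
                n_waters=int(kv.get("waters", 1)),
                occurrence=float(kv.get("occurrence", kv.get("_", 0.8))),
                correlation_time=float(kv.get("tau", 10.0))))
        elif kw == "chi":
            states = tuple(float(s) for s in kv.get("states", "-120,60").split(","))
            plan.chi = ChiProcess(states, float(kv.get("stay", 0.98)))
        elif kw == "census":
            plan.census = CensusPlant(
                fraction=float(kv.get("fraction", kv.get("_", 0.2))),
                correlation_time=float(kv.get("tau", 10.0)))
        elif kw == "noise":
            plan.noise_sigma = float(kv.get("sigma", kv.get("_", 0.05)))
        elif kw == "seed":
            plan.seed = int(kv.get("_", 0))
        else:
            raise ValueError(f"plan line {ln}: unknown directive {kw!r}")
    plan.__post_init__()
    return plan


# ---------------------------------------------------------------------------
# the toy complex

@dataclass
class _HBondStation:
    donor: int
    hydrogen: int
    acceptor: int
    acceptor_atoms: np.ndarray   # indices translated between on/off
    off_shift: np.ndarray


@dataclass
class _BridgeStation:
    n_partners: int
    n_waters: int
    partner_atoms: tuple[int, ...]
    water_atoms: list[np.ndarray]   # per water: its atom indices
    on_positions: list[np.ndarray]  # per water: (n_atoms, 3)
    park_positions: list[np.ndarray]


@dataclass
class _CensusStation:
    pro1_atoms: np.ndarray
    off_shift: np.ndarray


@dataclass
class ToyComplex:
    """A built toy complex plus the plant-station metadata the simulator
    needs."""

    topology: Topology
    coords: np.ndarray
    lesion_chain: str = "D"
    lesion_resnum: int = 0
    hbond_stations: list[_HBondStation] = field(default_factory=list)
    bridge_stations: list[_BridgeStation] = field(default_factory=list)
    census_station: _CensusStation | None = None
    chi_built: float = 0.0
    base_atom_indices: np.ndarray | None = None   # lesion base (rotates)
    chi_axis: tuple[int, int] = (0, 0)            # (C1', N9)

    @property
    def lesion(self):
        return self.topology.find_residue(self.lesion_chain, self.lesion_resnum)

    def catalytic_atoms(self):
        from .census import CatalyticAtoms
        top = self.topology
        return CatalyticAtoms(
            n_pro1=top.atom_index("A", 1, "N"),
            cd_pro1=top.atom_index("A", 1, "CD"),
            oe2_glu2=top.atom_index("A", 2, "OE2"),
            c1p_lesion=top.atom_index(self.lesion_chain, self.lesion_resnum, "C1'"),
            o4p_lesion=top.atom_index(self.lesion_chain, self.lesion_resnum, "O4'"),
            n9_lesion=top.atom_index(self.lesion_chain, self.lesion_resnum, "N9"),
        )


class _Builder:
    def __init__(self):
        self.records: list[AtomRecord] = []
        self.serial = 0

    def add(self, name, element, resname, resnum, chain, pos) -> int:
        self.serial += 1
        self.records.append(AtomRecord(
            serial=self.serial, name=name, element=element, alt_loc="",
            residue_name=resname, residue_number=resnum, chain_id=chain,
            coordinates=np.asarray(pos, dtype=float)))
        return self.serial - 1

    def add_residue(self, resname, resnum, chain, atoms: dict) -> dict:
        out = {}
        for name, pos in atoms.items():
            element = "H" if name.startswith("H") or (name[:1].isdigit() and
                                                      "H" in name[:2]) else name[0]
            out[name] = self.add(name, element, resname, resnum, chain, pos)
        return out


def _serine(origin, direction, h_toward, side=_Y):
    """A serine whose OG sits at ``origin`` with HG1 pointing ``h_toward``;
    the rest of the residue trails along ``-direction``."""
    d = _unit(np.asarray(direction, dtype=float))
    s = _unit(np.asarray(side, dtype=float) - (side @ d) * d)
    og = np.asarray(origin, dtype=float)
    cb = og - 1.43 * d
    ca = cb - 1.52 * _unit(d - 0.35 * s)
    n = ca - 1.47 * d
    c = ca - 1.52 * _unit(d + 0.9 * s)
    return {
        "N": n, "H": n - 1.0 * d, "CA": ca, "CB": cb, "OG": og,
        "HG1": og + 0.97 * _unit(h_toward), "C": c, "O": c - 1.23 * s,
    }


def _glycine_carbonyl(o_pos, outward, side=_Z):
    """A glycine whose backbone carbonyl O sits at ``o_pos``; the residue
    trails along ``outward`` (away from whatever the O accepts from)."""
    d = _unit(np.asarray(outward, dtype=float))
    s = _unit(np.asarray(side, dtype=float) - (side @ d) * d)
    c = o_pos + 1.23 * d
    ca = c + 1.52 * _unit(d + 0.4 * s)
    n = ca + 1.47 * _unit(d - 0.3 * s)
    return {"O": o_pos, "C": c, "CA": ca, "N": n, "H": n + 1.0 * d}


def build_toy_complex(n_bp: int = 14, n_protein: int = 8, n_waters: int = 5,
                      n_hbond_stations: int = 0,
                      bridge_station_specs: tuple = (),
                      opposite_base: str = "DC", kink_deg: float = 60.0,
                      propeller_deg: float = 0.0,
                      lesion_chi: float = -120.0) -> ToyComplex:
    """Build the toy complex: a kinked duplex with a central 8OG lesion, a
    protein scaffold with the catalytic-dyad stand-in, waters, a zinc ion,
    and as many isolated plant stations as requested.

    ``bridge_station_specs`` is a sequence of (n_partners, n_waters) pairs.
    Minimum sizes: 6 bp, 8 protein residues, 5 waters.
    """
    if n_bp < 6:
        raise ValueError("need at least a 6-bp duplex")
    if n_protein < 8:
        raise ValueError("need at least 8 protein residues (incl. the dyad)")
    if n_waters < 5:
        raise ValueError("need at least 5 waters")
    if opposite_base not in ("DC", "DA"):
        raise ValueError("opposite_base must be 'DC' or 'DA'")

    b = _Builder()
    half = np.radians(kink_deg / 2.0)
    d1 = np.array([np.cos(half), 0.0, np.sin(half)])
    d2 = np.array([np.cos(half), 0.0, -np.sin(half)])
    # damaged-strand sequence centered on the lesion, labels -7..+6 style
    lesion_pos = n_bp // 2
    seq = ["DA", "DT", "DG", "DC"] * (n_bp // 4 + 1)
    strand1 = [seq[i] for i in range(n_bp)]
    strand1[lesion_pos] = "8OG"
    labels = [i - lesion_pos for i in range(n_bp)]

    lesion_meta = {}
    strand2_records = []   # built now, added after strand 1 in 3'->5' order
    for i, resname in enumerate(strand1):
        t = i - (n_bp - 1) / 2.0
        axis = d1 if t < 0 else d2
        center = t * RISE * axis
        phi = np.radians(TWIST * i)
        e1 = _Y
        e2 = _unit(np.cross(axis, e1))
        radial = np.cos(phi) * e1 + np.sin(phi) * e2
        normal = _unit(np.cross(radial, np.cross(axis, radial)))  # ~axis
        # strand 1 nucleotide
        glyco1 = center + GLYCO_RADIUS * radial
        base1, anchor1 = _base_atoms_3d(resname, glyco1, -radial, normal)
        sugar1 = _sugar_atoms_3d(glyco1, radial, axis)
        # set chi exactly by rotating the base about C1'->N9(/N1)
        chi_target = lesion_chi if i == lesion_pos else -120.0
        base1 = _set_chi(base1, sugar1, anchor1, chi_target)
        # strand 2 nucleotide (antiparallel: base on the other side)
        comp = opposite_base if i == lesion_pos else COMPLEMENT[resname]
        glyco2 = center - GLYCO_RADIUS * radial
        base2, anchor2 = _base_atoms_3d(comp, glyco2, radial, -normal)
        sugar2 = _sugar_atoms_3d(glyco2, -radial, -axis)
        base2 = _set_chi(base2, sugar2, anchor2, -120.0)
        # slide strand 2 along the pair axis for a realistic WC gap
        shift = _wc_shift(base1, base2, radial)
        base2 = {k: v + shift for k, v in base2.items()}
        sugar2 = {k: v + shift for k, v in sugar2.items()}
        if propeller_deg:
            # counter-rotate the two bases about the pair long axis
            # (purine C8 -> pyrimidine C6, centroid axis otherwise)
            if anchor1 == "N9" and anchor2 == "N1":
                paxis = base2["C6"] - base1["C8"]
            elif anchor1 == "N1" and anchor2 == "N9":
                paxis = base1["C6"] - base2["C8"]
            else:
                paxis = (np.mean(list(base2.values()), axis=0)
                         - np.mean(list(base1.values()), axis=0))
            base1 = _rotate_about(base1, glyco1, paxis, +propeller_deg / 2.0)
            base2 = _rotate_about(base2, glyco2 + shift, paxis,
                                  -propeller_deg / 2.0)
        atoms1 = {**sugar1, **base1}
        idx1 = b.add_residue(resname, labels[i], "D", atoms1)
        strand2_records.append((comp, labels[i], {**sugar2, **base2}))
        if i == lesion_pos:
            lesion_meta = {"idx": idx1, "base_names": set(base1),
                           "chi": chi_target}

    # strand 2 in its own 5'->3' order (reverse of strand 1)
    for comp, lab, atoms in reversed(strand2_records):
        b.add_residue(comp, lab, "E", atoms)

    # protein scaffold: catalytic dyad near the lesion, filler on a line
    les_c1 = b.records[lesion_meta["idx"]["C1'"]].coordinates
    les_o4 = b.records[lesion_meta["idx"]["O4'"]].coordinates
    u = _unit(les_c1 - les_o4)
    w = _unit(np.cross(u, _Y)) if abs(u @ _Y) < 0.9 else _unit(np.cross(u, _Z))
    n_pro = les_c1 + 3.5 * u
    cd_dir = np.cos(np.radians(107.0)) * (-u) + np.sin(np.radians(107.0)) * w
    cd = n_pro + 1.5 * cd_dir
    ca = n_pro + 1.47 * _unit(w - 0.3 * u)
    cg = (ca + cd) / 2.0 + 0.45 * _unit(np.cross(u, w))
    cbeta = ca + 1.52 * _unit(cg - ca + 0.3 * w)
    c_pro = ca + 1.52 * _unit(u + w)
    pro1 = {"N": n_pro, "CA": ca, "CB": cbeta, "CG": cg, "CD": cd,
            "C": c_pro, "O": c_pro + 1.23 * u}
    pro1_idx = b.add_residue("PRO", 1, "A", pro1)

    v2 = _unit(np.cross(u, w))
    oe2 = les_o4 + 4.0 * v2
    cd_glu = oe2 + 1.25 * _unit(v2 + 0.4 * w)
    oe1 = cd_glu + 1.25 * _unit(v2 - 0.8 * w)
    cg_glu = cd_glu + 1.52 * v2
    cb_glu = cg_glu + 1.52 * _unit(v2 + 0.3 * u)
    ca_glu = cb_glu + 1.52 * v2
    n_glu = ca_glu + 1.47 * _unit(v2 - 0.4 * w)
    c_glu = ca_glu + 1.52 * _unit(v2 + 0.4 * w)
    glu2 = {"N": n_glu, "H": n_glu + 1.0 * v2, "CA": ca_glu, "CB": cb_glu,
            "CG": cg_glu, "CD": cd_glu, "OE1": oe1, "OE2": oe2,
            "C": c_glu, "O": c_glu + 1.23 * v2}
    b.add_residue("GLU", 2, "A", glu2)

    filler_names = ["ARG", "PHE", "GLY", "ALA", "SER", "GLY"]
    while len(filler_names) < n_protein - 2:
        filler_names.append("GLY")
    for j, rn in enumerate(filler_names[: n_protein - 2]):
        base_pos = np.array([-12.0 + 3.8 * j, 16.0, 6.0])
        res = {"N": base_pos, "CA": base_pos + np.array([1.0, 1.0, 0.2]),
               "C": base_pos + np.array([2.2, 0.4, 0.0]),
               "O": base_pos + np.array([2.6, 0.4, 1.15])}
        if rn != "PRO":
            res["H"] = base_pos + np.array([0.0, -1.0, 0.0])
        ca = res["CA"]
        if rn == "ARG":
            res.update({"CB": ca + np.array([0, 1.4, 0.6]),
                        "CG": ca + np.array([0, 2.6, 1.2]),
                        "CD": ca + np.array([0, 3.8, 1.8]),
                        "NE": ca + np.array([0, 5.0, 2.2]),
                        "HE": ca + np.array([0.9, 5.3, 2.3]),
                        "CZ": ca + np.array([0, 6.2, 2.7]),
                        "NH1": ca + np.array([1.1, 6.9, 2.9]),
                        "HH11": ca + np.array([1.2, 7.9, 3.0]),
                        "NH2": ca + np.array([-1.1, 6.9, 2.9]),
                        "HH21": ca + np.array([-1.2, 7.9, 3.0])})
        elif rn == "PHE":
            ring = _polygon(6, 1.39)
            cg = ca + np.array([0, 1.5, 0.8])
            res["CB"] = ca + np.array([0, 1.2, 0.2])
            for nm, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ring):
                res[nm] = cg + np.array([p[0], 1.0 + p[1], 1.2])
        elif rn == "SER":
            res.update({"OG": ca + np.array([0, 1.4, 0.3]),
                        "HG1": ca + np.array([0, 2.3, 0.1])})
        b.add_residue(rn, 3 + j, "A", res)

    # hydrogen-bond plant stations (isolated donor/acceptor serine pairs)
    hbond_meta = []
    for i in range(n_hbond_stations):
        s = np.array([55.0, 0.0, 14.0 * i])
        don = _serine(s, _X, _X)
        acc = _serine(s + HB_ON * _X, -_X, _X)
        di = b.add_residue("SER", 101 + 2 * i, "A", don)
        ai = b.add_residue("SER", 102 + 2 * i, "A", acc)
        hbond_meta.append((di, ai))

    # bridge stations
    bridge_meta = []
    for j, (npart, nwat) in enumerate(bridge_station_specs):
        c = np.array([-20.0 + 24.0 * j, 34.0, 0.0])
        partners = []
        gly_resnum = 201 + 10 * j
        if nwat == 1:
            az = np.radians(52.25)
            dirs = [np.array([np.cos(az), np.sin(az), 0.0]),
                    np.array([np.cos(az), -np.sin(az), 0.0])]
            water_on = [c]
            for d in dirs:
                gi = b.add_residue("GLY", gly_resnum, "A",
                                   _glycine_carbonyl(c + HB_ON * d, d))
                partners.append(gi["O"])
                gly_resnum += 1
            if npart == 3:
                og = c - HB_ON * _X
                si = b.add_residue("SER", gly_resnum, "A",
                                   _serine(og, _X, _X))
                partners.append(si["OG"])
                gly_resnum += 1
        else:  # two waters bridging two partners
            a_off = 2.29
            h_off = np.sqrt(HB_ON ** 2 - a_off ** 2)
            p1 = c + a_off * _Y
            p2 = c - a_off * _Y
            for pp, d in ((p1, _Y), (p2, -_Y)):
                gi = b.add_residue("GLY", gly_resnum, "A",
                                   _glycine_carbonyl(pp, d))
                partners.append(gi["O"])
                gly_resnum += 1
            water_on = [c + h_off * _Z, c - h_off * _Z]
            if npart == 3:
                raise ValueError("two-water stations support 2 partners")
        bridge_meta.append((npart, nwat, tuple(partners), c, water_on))

    # bridge waters + free waters
    water_resnum = 301
    bridge_water_atoms = []
    for j, (npart, nwat, partners, c, water_on) in enumerate(bridge_meta):
        atoms_per_water = []
        for widx, wpos in enumerate(water_on):
            targets = [b.records[p].coordinates for p in partners[:2]]
            h1 = wpos + 0.96 * _unit(targets[0] - wpos)
            h2 = wpos + 0.96 * _unit(targets[1] - wpos)
            wi = b.add_residue("HOH", water_resnum, "W",
                               {"O": wpos, "H1": h1, "H2": h2})
            atoms_per_water.append(np.array(sorted(wi.values())))
            water_resnum += 1
        bridge_water_atoms.append(atoms_per_water)
    n_bridge_waters = sum(len(a) for a in bridge_water_atoms)
    for k in range(max(0, n_waters - n_bridge_waters)):
        o = np.array([8.0 * k, -26.0, 0.0])
        b.add_residue("HOH", 401 + k, "W",
                      {"O": o, "H1": o + np.array([0.76, 0.59, 0.0]),
                       "H2": o + np.array([-0.76, 0.59, 0.0])})

    b.add("ZN", "ZN", "ZN", 300, "Z", np.array([4.0, 20.0, -4.0]))

    topology = Topology(b.records)
    coords = np.array([r.coordinates for r in b.records])
    classify_residues(topology, coords=coords)

    toy = ToyComplex(topology, coords)
    toy.lesion_resnum = 0
    toy.chi_built = lesion_meta["chi"]
    les = toy.lesion
    toy.base_atom_indices = np.array(
        [i for i in les.atom_indices
         if topology.names[i] in lesion_meta["base_names"]])
    toy.chi_axis = (topology.atom_in_residue(les, "C1'"),
                    topology.atom_in_residue(les, "N9"))

    for di, ai in hbond_meta:
        toy.hbond_stations.append(_HBondStation(
            donor=di["OG"], hydrogen=di["HG1"], acceptor=ai["OG"],
            acceptor_atoms=np.array(sorted(ai.values())),
            off_shift=(HB_OFF - HB_ON) * _X))
    for (npart, nwat, partners, c, water_on), watoms in zip(
            bridge_meta, bridge_water_atoms):
        parks = []
        for widx, wa in enumerate(watoms):
            park_origin = c + np.array([0.0, 26.0, 6.0 * widx])
            parks.append(coords[wa] - coords[wa[0]] + park_origin)
        toy.bridge_stations.append(_BridgeStation(
            n_partners=npart, n_waters=nwat, partner_atoms=partners,
            water_atoms=watoms, on_positions=[coords[wa] for wa in watoms],
            park_positions=parks))
    pro1_atoms = np.array(sorted(pro1_idx.values()))
    toy.census_station = _CensusStation(pro1_atoms=pro1_atoms,
                                        off_shift=2.0 * u)
    return toy


def _set_chi(base: dict, sugar: dict, anchor: str, chi: float) -> dict:
    """Rotate base atoms about the glycosidic bond to the target chi."""
    from .geometry import torsion_values

    c1 = sugar["C1'"]
    o4 = sugar["O4'"]
    gn = base[anchor]
    ref = base["C4"] if anchor == "N9" else base["C2"]
    cur, ok = torsion_values(o4[None], c1[None], gn[None], ref[None])
    delta = chi - float(cur[0])
    return _rotate_about(base, gn, gn - c1, delta)


def _rotate_about(atoms: dict, origin, axis, deg) -> dict:
    r = _rot(axis, deg)
    return {k: origin + r @ (v - origin) for k, v in atoms.items()}


def _wc_shift(base1: dict, base2: dict, radial) -> np.ndarray:
    """Slide for strand 2 so the paired bases' closest heavy atoms sit at
    the WC-gap distance along the pair axis."""
    heavy1 = np.array([v for k, v in base1.items() if not k.startswith("H")])
    heavy2 = np.array([v for k, v in base2.items() if not k.startswith("H")])
    d = np.linalg.norm(heavy1[:, None] - heavy2[None], axis=2)
    gap = d.min()
    return (WC_GAP - gap) * (-_unit(np.asarray(radial, dtype=float)))


# ---------------------------------------------------------------------------
# trajectory simulation

@dataclass
class TruthManifest:
    """Realized per-snapshot state of every plant (exact ground truth)."""

    seed: int
    n_snapshots: int
    hbond_keys: list[HBondKey]
    hbond_states: np.ndarray            # (n_plants, n_snapshots) bool
    bridge_partner_sets: list[tuple]
    bridge_kinds: list[str]
    bridge_n_waters: list[int]
    bridge_states: np.ndarray
    chi_state_index: np.ndarray | None  # (n_snapshots,) int
    chi_state_values: tuple[float, ...] | None
    census_mask: np.ndarray | None

    @property
    def hbond_counts(self) -> np.ndarray:
        return self.hbond_states.sum(axis=1)

    @property
    def hbond_occurrences(self) -> np.ndarray:
        return self.hbond_counts / self.n_snapshots

    @property
    def bridge_counts(self) -> np.ndarray:
        return self.bridge_states.sum(axis=1)

    def chi_state_fractions(self) -> np.ndarray | None:
        if self.chi_state_index is None:
            return None
        k = len(self.chi_state_values)
        return np.bincount(self.chi_state_index, minlength=k) / self.n_snapshots

    def to_text(self) -> str:
        lines = [f"# truth manifest (seed {self.seed}, "
                 f"{self.n_snapshots} snapshots)"]
        lines.append("kind\tid\ttarget_partner\tcount\toccurrence")
        for key, c in zip(self.hbond_keys, self.hbond_counts):
            lines.append(f"hbond\t{key.donor}-{key.acceptor}\t-\t{c}\t"
                         f"{c / self.n_snapshots:.6f}")
        for ps, kind, c in zip(self.bridge_partner_sets, self.bridge_kinds,
                               self.bridge_counts):
            label = "|".join(":".join(map(str, p)) for p in ps)
            lines.append(f"bridge\t{kind}\t{label}\t{c}\t"
                         f"{c / self.n_snapshots:.6f}")
        if self.census_mask is not None:
            c = int(self.census_mask.sum())
            lines.append(f"census\toptimal\t-\t{c}\t"
                         f"{c / self.n_snapshots:.6f}")
        if self.chi_state_index is not None:
            for v, f in zip(self.chi_state_values, self.chi_state_fractions()):
                lines.append(f"chi\tstate_{v:g}\t-\t-\t{f:.6f}")
        return "\n".join(lines) + "\n"


def _markov_chain(rng, n: int, p: float, tau: float) -> np.ndarray:
    """Two-state (on/off) chain with stationary P(on) = p and relaxation
    time ~tau snapshots."""
    if p <= 0.0:
        return np.zeros(n, dtype=bool)
    if p >= 1.0:
        return np.ones(n, dtype=bool)
    tau = max(tau, 1.0)
    q_on = min(1.0, p / tau)        # off -> on
    q_off = min(1.0, (1.0 - p) / tau)  # on -> off
    u = rng.random(n)
    out = np.empty(n, dtype=bool)
    state = bool(u[0] < p)
    out[0] = state
    for i in range(1, n):
        state = not (u[i] < q_off) if state else bool(u[i] < q_on)
        out[i] = state
    return out


def simulate_trajectory(toy: ToyComplex, plan: PlantSpec, n_snapshots: int,
                        dt_ps: float = 2.0, label: str = ""
                        ) -> tuple[Trajectory, TruthManifest]:
    """Realize the plant plan as a coordinate trajectory plus exact truth.

    Planted hydrogen bonds toggle the acceptor residue between the ideal
    and broken station positions; bridge waters jump between bridging and
    parked positions; the lesion base rotates to the chi-process state; the
    Pro1 stand-in shuttles between optimal and non-optimal attack geometry;
    Gaussian noise (sigma per coordinate) is added last.  Byte-identical
    for a fixed plan (including its seed).
    """
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    if len(plan.hbonds) > len(toy.hbond_stations):
        raise ValueError(
            f"plan has {len(plan.hbonds)} hydrogen-bond plants but the "
            f"complex was built with {len(toy.hbond_stations)} stations")
    if len(plan.bridges) > len(toy.bridge_stations):
        raise ValueError("plan has more bridge plants than stations")
    for plant, station in zip(plan.bridges, toy.bridge_stations):
        if (plant.n_partners, plant.n_waters) != (station.n_partners,
                                                  station.n_waters):
            raise ValueError(
                f"bridge plant ({plant.n_partners} partners, "
                f"{plant.n_waters} waters) does not match its station "
                f"({station.n_partners}, {station.n_waters})")
    rng = np.random.default_rng(plan.seed)

    hb_states = np.array([
        _markov_chain(rng, n_snapshots, p.occurrence, p.correlation_time)
        for p in plan.hbonds]).reshape(len(plan.hbonds), n_snapshots)
    br_states = np.array([
        _markov_chain(rng, n_snapshots, p.occurrence, p.correlation_time)
        for p in plan.bridges]).reshape(len(plan.bridges), n_snapshots)
    census_mask = None
    if plan.census is not None:
        census_mask = _markov_chain(rng, n_snapshots, plan.census.fraction,
                                    plan.census.correlation_time)
    chi_idx = None
    if plan.chi is not None:
        k = len(plan.chi.states)
        chi_idx = np.empty(n_snapshots, dtype=int)
        chi_idx[0] = rng.integers(k)
        stay = plan.chi.stay_probability
        for i in range(1, n_snapshots):
            if rng.random() < stay:
                chi_idx[i] = chi_idx[i - 1]
            else:
                others = [s for s in range(k) if s != chi_idx[i - 1]]
                chi_idx[i] = others[rng.integers(len(others))] if others \
                    else chi_idx[i - 1]

    base = toy.coords
    n_atoms = base.shape[0]
    coords = np.repeat(base[None], n_snapshots, axis=0)

    for pi, station in enumerate(toy.hbond_stations[: len(plan.hbonds)]):
        off = ~hb_states[pi]
        coords[np.ix_(off, station.acceptor_atoms)] += station.off_shift
    for pi, station in enumerate(toy.bridge_stations[: len(plan.bridges)]):
        off = ~br_states[pi]
        for wa, park in zip(station.water_atoms, station.park_positions):
            coords[np.ix_(off, wa)] = park
    if census_mask is not None and toy.census_station is not None:
        off = ~census_mask
        coords[np.ix_(off, toy.census_station.pro1_atoms)] += \
            toy.census_station.off_shift
    if chi_idx is not None:
        c1, n9 = toy.chi_axis
        axis = _unit(base[n9] - base[c1])
        origin = base[n9]
        rel = base[toy.base_atom_indices] - origin
        for s, chi_val in enumerate(plan.chi.states):
            rot = _rot(axis, chi_val - toy.chi_built)
            sel = np.flatnonzero(chi_idx == s)
            if sel.size:
                coords[np.ix_(sel, toy.base_atom_indices)] = \
                    origin + rel @ rot.T
    if plan.noise_sigma > 0:
        coords += rng.normal(0.0, plan.noise_sigma, size=coords.shape)

    traj = Trajectory(toy.topology, coords, dt_ps=dt_ps, label=label)

    from .waters import BridgeParams, partner_label
    bp = BridgeParams()
    partner_sets = []
    kinds = []
    for station in toy.bridge_stations[: len(plan.bridges)]:
        labels = tuple(sorted(partner_label(toy.topology, a, bp)
                              for a in station.partner_atoms))
        partner_sets.append(labels)
        kinds.append("pair" if station.n_partners == 2 else "triplet")
    manifest = TruthManifest(
        seed=plan.seed, n_snapshots=n_snapshots,
        hbond_keys=[HBondKey(s.donor, s.acceptor)
                    for s in toy.hbond_stations[: len(plan.hbonds)]],
        hbond_states=hb_states,
        bridge_partner_sets=partner_sets, bridge_kinds=kinds,
        bridge_n_waters=[s.n_waters
                         for s in toy.bridge_stations[: len(plan.bridges)]],
        bridge_states=br_states,
        chi_state_index=chi_idx,
        chi_state_values=plan.chi.states if plan.chi else None,
        census_mask=census_mask)
    return traj, manifest
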