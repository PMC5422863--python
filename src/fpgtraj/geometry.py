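"""Per-snapshot structural descriptors for protein-DNA trajectories.

Everything a study of a glycosylase pre-catalytic complex plots against
time lives here: interatomic distances, three-point angles, torsions
(IUPAC sign convention, values in (-180, 180]), the glycosidic angle chi
with syn/anti conformer classification, Kabsch least-squares superposition
and r.m.s.d., radius of gyration, the DNA kink angle from per-arm principal
axes of the phosphate trace, base-pair propeller twist, the base-eversion
pseudo-dihedral, and (possibly circular) moving averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .topology import Residue, Topology, Trajectory

DEG = 180.0 / np.pi


@dataclass
class GeometrySeries:
    """A named per-snapshot scalar aligned to a trajectory."""

    name: str
    unit: str  # one of {"angstrom", "degree", "angstrom2", "dimensionless"}
    values: np.ndarray
    mask: np.ndarray | None = None  # True where the value is valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must be aligned")

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# elementary vector measures (vectorized over snapshots)

def _vec_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between batches of vectors, degrees in [0, 180]."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def distance_series(traj: Trajectory, atom_a: int, atom_b: int,
                    name: str | None = None) -> GeometrySeries:
    d = np.linalg.norm(traj.coords[:, atom_a] - traj.coords[:, atom_b], axis=1)
    return GeometrySeries(name or f"d({atom_a},{atom_b})", "angstrom", d)


def angle_series(traj: Trajectory, a: int, b: int, c: int,
                 name: str | None = None) -> GeometrySeries:
    """Three-point angle a-b-c in degrees, [0, 180]."""
    u = traj.coords[:, a] - traj.coords[:, b]
    v = traj.coords[:, c] - traj.coords[:, b]
    return GeometrySeries(name or f"angle({a},{b},{c})", "degree", _vec_angle(u, v))


def torsion_values(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed dihedral (degrees, (-180, 180]) for batches of four points.

    Returns (values, valid_mask); a collinear or near-zero central axis
    masks the value instead of raising.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    valid = (b2n > 1e-9) & (np.linalg.norm(n1, axis=-1) > 1e-12) \
        & (np.linalg.norm(n2, axis=-1) > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.einsum("...i,...i->...", n1, n2)
        y = np.einsum("...i,...i->...", np.cross(n1, n2), b2 / b2n[..., None])
    ang = np.degrees(np.arctan2(y, x))
    # report torsions in (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang, valid


def torsion_series(traj: Trajectory, a: int, b: int, c: int, d: int,
                   name: str | None = None) -> GeometrySeries:
    vals, valid = torsion_values(traj.coords[:, a], traj.coords[:, b],
                                 traj.coords[:, c], traj.coords[:, d])
    return GeometrySeries(name or f"torsion({a},{b},{c},{d})", "degree",
                          vals, mask=valid)


# ---------------------------------------------------------------------------
# glycosidic angle and conformer domains

#: purine ring atoms in plane-fit order; the first six suffice for normals
PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "C6", "N1", "C2", "N3")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def _chi_atoms(topology: Topology, residue: Residue,
               o4_name: str | None = None) -> tuple[int, int, int, int]:
    names = {topology.names[i]: int(i) for i in residue.atom_indices}
    o4 = None
    candidates = [o4_name] if o4_name else ["O4'", "O4*", "C4*", "C10"]
    for cand in candidates:
        if cand in names:
            o4 = names[cand]
            break
    if o4 is None or "C1'" not in names:
        raise ValueError(
            f"residue {residue.chain_id}:{residue.number}:{residue.name} "
            f"lacks the sugar atoms (O4'/isostere, C1') needed for chi")
    if "N9" in names:  # purine: O4'-C1'-N9-C4
        if "C4" not in names:
            raise ValueError(f"purine residue {residue.name} lacks C4")
        return o4, names["C1'"], names["N9"], names["C4"]
    if "N1" in names and "C2" in names:  # pyrimidine: O4'-C1'-N1-C2
        return o4, names["C1'"], names["N1"], names["C2"]
    raise ValueError(
        f"residue {residue.chain_id}:{residue.number}:{residue.name} "
        f"has no recognizable glycosidic nitrogen (N9 or N1)")


def glycosidic_chi(traj: Trajectory, residue: Residue,
                   o4_name: str | None = None) -> GeometrySeries:
    """Glycosidic torsion chi: O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for
    pyrimidines; for carbacyclic analogs the atom isosteric to O4' is used
    (override via ``o4_name``)."""
    a, b, c, d = _chi_atoms(traj.topology, residue, o4_name)
    s = torsion_series(traj, a, b, c, d)
    s.name = f"chi({residue.chain_id}:{residue.number}:{residue.name})"
    return s


@dataclass
class ConformerDomains:
    """Angular domains for chi classification (degrees).

    ``syn`` is the open-ended interval (syn_lo, syn_hi); everything else in
    (-180, 180] is ``anti`` (half-open convention: a boundary value such as
    exactly +90 is anti).  ``high_anti`` and ``high_syn`` are border
    sub-ranges reported alongside the primary label, mirroring the usage in
    the structural literature where chi near the syn/anti divide is called
    "high anti" (around -64) or "high syn" (around +101).
    """

    syn_lo: float = -90.0
    syn_hi: float = 90.0
    high_anti: tuple[float, float] = (-90.0, -30.0)
    high_syn: tuple[float, float] = (60.0, 120.0)

    def classify(self, chi: float) -> str:
        c = _wrap_angle(chi)
        return "syn" if self.syn_lo < c < self.syn_hi else "anti"

    def sublabel(self, chi: float) -> str | None:
        c = _wrap_angle(chi)
        if self.high_anti[0] < c <= self.high_anti[1]:
            return "high_anti"
        if self.high_syn[0] < c <= self.high_syn[1]:
            return "high_syn"
        return None


def _wrap_angle(a):
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return w if w.ndim else float(w)


def classify_chi(chi, domains: ConformerDomains | None = None):
    """Primary syn/anti label (scalar in -> str out, array in -> object array)."""
    domains = domains or ConformerDomains()
    if np.ndim(chi) == 0:
        return domains.classify(float(chi))
    return np.array([domains.classify(c) for c in np.asarray(chi, dtype=float)],
                    dtype=object)


# ---------------------------------------------------------------------------
# superposition and r.m.s.d.

def superpose_kabsch(reference: np.ndarray, mobile: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    (weighted) least-squares sense; the rotation is proper (det +1).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    ref_c = ref - (w[:, None] * ref).sum(0) / wsum
    mob_c = mob - (w[:, None] * mob).sum(0) / wsum
    h = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("rank-deficient (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = mob_c @ rot.T
    rmsd = float(np.sqrt((w * ((fitted - ref_c) ** 2).sum(1)).sum() / wsum))
    ref_mean = (w[:, None] * ref).sum(0) / wsum
    mob_mean = (w[:, None] * mob).sum(0) / wsum
    trans = ref_mean - rot @ mob_mean
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, reference_snapshot: np.ndarray,
                fit_selection: np.ndarray, measure_selection: np.ndarray,
                name: str = "rmsd") -> GeometrySeries:
    """Per snapshot: superpose on ``fit_selection``, report r.m.s.d. over
    ``measure_selection`` (both are atom-index arrays)."""
    fit = np.asarray(fit_selection, dtype=int)
    mea = np.asarray(measure_selection, dtype=int)
    if fit.size == 0 or mea.size == 0:
        raise ValueError("empty selection")
    ref = np.asarray(reference_snapshot, dtype=float)
    out = np.empty(traj.n_snapshots)
    for si in range(traj.n_snapshots):
        rot, trans, _ = superpose_kabsch(ref[fit], traj.coords[si, fit])
        moved = traj.coords[si, mea] @ rot.T + trans
        out[si] = np.sqrt(((moved - ref[mea]) ** 2).sum(1).mean())
    return GeometrySeries(name, "angstrom", out)


def radius_of_gyration(traj: Trajectory, selection: np.ndarray,
                       mass_weighted: bool = False) -> GeometrySeries:
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    if mass_weighted:
        w = np.array([T.ATOMIC_MASSES.get(e, T.MASS_DEFAULT)
                      for e in traj.topology.elements[sel]])
    else:
        w = np.ones(sel.size)
    xyz = traj.coords[:, sel]
    com = (w[None, :, None] * xyz).sum(1) / w.sum()
    rg = np.sqrt((w[None, :] * ((xyz - com[:, None]) ** 2).sum(2)).sum(1) / w.sum())
    return GeometrySeries("radius_of_gyration", "angstrom", rg)


# ---------------------------------------------------------------------------
# DNA descriptors

def _arm_axis(points: np.ndarray) -> np.ndarray | None:
    """Oriented arm direction: the least-squares linear trend of position
    against point order.  Unlike a raw principal component, the trend is
    insensitive to the lateral (radial) spread of helical phosphate
    positions — over a half-turn arm the largest-variance direction of the
    P cloud is sideways, not axial — and it carries the 5'->3' orientation
    automatically.  None for degenerate (coincident) clouds."""
    n = points.shape[0]
    o = np.arange(n) - (n - 1) / 2.0
    axis = o @ (points - points.mean(0))
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return None
    return axis / norm


def dna_kink_angle(traj: Trajectory, arm1_selection: np.ndarray,
                   arm2_selection: np.ndarray) -> GeometrySeries:
    """Kink of the DNA axis from the two arms' oriented P-atom axes.

    Each arm selection is an atom-index array of P atoms ordered along the
    helix (bp by bp; including both strands' P per base pair makes the
    axis fit robust to helical phase).  The per-arm axis is the linear
    trend of P position vs order, and the kink is the angle between the two
    oriented axes: 0 for straight DNA, ~60 degrees for the sharp
    glycosylase-induced bend.
    """
    a1 = np.asarray(arm1_selection, dtype=int)
    a2 = np.asarray(arm2_selection, dtype=int)
    if a1.size < 3 or a2.size < 3:
        raise ValueError("each arm needs at least 3 P atoms")
    vals = np.empty(traj.n_snapshots)
    mask = np.ones(traj.n_snapshots, dtype=bool)
    for si in range(traj.n_snapshots):
        u = _arm_axis(traj.coords[si, a1])
        v = _arm_axis(traj.coords[si, a2])
        if u is None or v is None:
            vals[si], mask[si] = np.nan, False
            continue
        vals[si] = _vec_angle(u, v)
    return GeometrySeries("dna_kink", "degree", vals, mask=mask)


def _ring_atoms(topology: Topology, residue: Residue) -> np.ndarray:
    names = {topology.names[i]: int(i) for i in residue.atom_indices}
    ring = PURINE_RING if "N9" in names else PYRIMIDINE_RING
    idx = [names[n] for n in ring if n in names]
    if len(idx) < 3:
        raise ValueError(
            f"residue {residue.chain_id}:{residue.number}:{residue.name} "
            f"has fewer than 3 recognizable ring atoms")
    return np.array(idx, dtype=int)


def _plane_normal(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[-1]


def propeller_twist(traj: Trajectory, base_pair: tuple[Residue, Residue]
                    ) -> GeometrySeries:
    """Propeller twist omega of a base pair: the signed counter-rotation of
    the two base planes about the pair long axis.

    The long axis runs C8(purine) -> C6(pyrimidine) (centroid-to-centroid
    for like-type pairs).  The sign convention is fixed by orienting the
    first base's normal with the chirality of its glycosidic attachment, so
    that canonical B-DNA comes out positive (~ +13 degrees).
    """
    res_a, res_b = base_pair
    top = traj.topology
    ring_a = _ring_atoms(top, res_a)
    ring_b = _ring_atoms(top, res_b)
    names_a = {top.names[i]: int(i) for i in res_a.atom_indices}
    names_b = {top.names[i]: int(i) for i in res_b.atom_indices}

    def _axis_pts(si):
        if "N9" in names_a and "N9" not in names_b:
            return traj.coords[si, names_a["C8"]], traj.coords[si, names_b["C6"]]
        if "N9" in names_b and "N9" not in names_a:
            return traj.coords[si, names_b["C6"]], traj.coords[si, names_a["C8"]]
        return (traj.coords[si, ring_a].mean(0), traj.coords[si, ring_b].mean(0))

    anchor_a = names_a.get("C1'", ring_a[0])
    vals = np.empty(traj.n_snapshots)
    mask = np.ones(traj.n_snapshots, dtype=bool)
    for si in range(traj.n_snapshots):
        pa = traj.coords[si, ring_a]
        pb = traj.coords[si, ring_b]
        start, end = _axis_pts(si)
        axis = end - start
        nax = np.linalg.norm(axis)
        if nax < 1e-9:
            vals[si], mask[si] = np.nan, False
            continue
        axis = axis / nax
        n1 = _plane_normal(pa)
        n2 = _plane_normal(pb)
        # orient n1 deterministically from the glycosidic-attachment chirality
        chir = np.cross(axis, traj.coords[si, anchor_a] - pa.mean(0))
        if np.dot(n1, chir) < 0:
            n1 = -n1
        if np.dot(n2, n1) < 0:
            n2 = -n2
        p1 = n1 - np.dot(n1, axis) * axis
        p2 = n2 - np.dot(n2, axis) * axis
        if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
            vals[si], mask[si] = np.nan, False
            continue
        vals[si] = np.degrees(np.arctan2(np.dot(np.cross(p1, p2), axis),
                                         np.dot(p1, p2)))
    return GeometrySeries("propeller_twist", "degree", vals, mask=mask)


# ---------------------------------------------------------------------------
# eversion pseudo-dihedral

@dataclass
class EversionDefinition:
    """Four reference points for the base-eversion pseudo-dihedral.

    Each point is either a single atom index or an index array (centroid).
    Absolute eversion values are comparable only within one definition.
    """

    points: tuple = ()

    @classmethod
    def default_for(cls, topology: Topology, lesion: Residue
                    ) -> "EversionDefinition":
        """Base ring centroid, C1' and P of the lesion, P of the 3' neighbor
        (next residue in chain order)."""
        ring = _ring_atoms(topology, lesion)
        c1 = topology.atom_in_residue(lesion, "C1'")
        p = topology.atom_in_residue(lesion, "P")
        ri = topology.residues.index(lesion)
        neighbors = [r for r in topology.residues[ri + 1: ri + 2]
                     if r.chain_id == lesion.chain_id]
        if not neighbors:
            raise ValueError("lesion has no 3' neighbor in its chain")
        p3 = topology.atom_in_residue(neighbors[0], "P")
        return cls(points=(ring, c1, p, p3))


def eversion_angle(traj: Trajectory, lesion: Residue,
                   definition: EversionDefinition | None = None
                   ) -> GeometrySeries:
    """Pseudo-dihedral over the four configured reference points, tracking
    how far the damaged nucleotide has flipped out of the helix."""
    definition = definition or EversionDefinition.default_for(traj.topology, lesion)
    if len(definition.points) != 4:
        raise ValueError("eversion definition needs exactly 4 points")
    pts = []
    for p in definition.points:
        if np.ndim(p) == 0:
            pts.append(traj.coords[:, int(p)])
        else:
            pts.append(traj.coords[:, np.asarray(p, dtype=int)].mean(1))
    vals, valid = torsion_values(*pts)
    return GeometrySeries("eversion", "degree", vals, mask=valid)


# ---------------------------------------------------------------------------
# moving averages

def moving_average(series: GeometrySeries, window: int = 50,
                   circular: bool | None = None) -> GeometrySeries:
    """Centered moving mean over valid values; circular (vector) averaging
    for angular series.  Output is masked where a window holds no valid
    points."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(series)
    if window > n:
        warnings.warn("moving-average window exceeds series length; "
                      "output fully masked")
        return GeometrySeries(series.name, series.unit, np.full(n, np.nan),
                              mask=np.zeros(n, dtype=bool))
    if circular is None:
        circular = series.unit == "degree"
    half_lo = (window - 1) // 2
    half_hi = window - 1 - half_lo
    valid = series.mask.astype(float)
    if circular:
        rad = np.radians(np.where(series.mask, series.values, 0.0))
        comp = (np.cos(rad) * valid, np.sin(rad) * valid)
    else:
        comp = (np.where(series.mask, series.values, 0.0) * 1.0,)

    def _winsum(x):
        c = np.concatenate([[0.0], np.cumsum(x)])
        lo = np.maximum(np.arange(n) - half_lo, 0)
        hi = np.minimum(np.arange(n) + half_hi + 1, n)
        return c[hi] - c[lo]

    counts = _winsum(valid)
    out_mask = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        if circular:
            cx = _winsum(comp[0]) / counts
            sx = _winsum(comp[1]) / counts
            vals = np.degrees(np.arctan2(sx, cx))
            vals = np.where(vals <= -180.0, vals + 360.0, vals)
        else:
            vals = _winsum(comp[0]) / counts
    vals = np.where(out_mask, vals, np.nan)
    return GeometrySeries(series.name, series.unit, vals, mask=out_mask)
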