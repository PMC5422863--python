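"""Solvent-accessible surface areas by the Shrake-Rupley method.

Sphere points come from a deterministic golden-section spiral (no RNG), so
areas are exactly reproducible for a fixed point count.  On top of the raw
per-atom areas the module provides the two derived quantities used when
characterizing a protein-DNA interface: the solvent-exposure fraction of a
water molecule (buried waters have < 10% exposure) and the occluded contact
area between two atom groups (the surface each loses to the other, averaged
over the pair, with only the two groups present).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import templates as T
from .geometry import GeometrySeries
from .topology import Residue, Trajectory


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral point set on the unit sphere."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def atom_radii(elements) -> np.ndarray:
    """Van der Waals radii for an element array (bundled Bondi table)."""
    return np.array([T.VDW_RADII.get(str(e).upper(), T.VDW_DEFAULT)
                     for e in elements])


def sasa(coords: np.ndarray, radii: np.ndarray,
         selection: np.ndarray | None = None,
         context_selection: np.ndarray | None = None,
         probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley SASA (Angstrom^2) of ``selection`` atoms in the presence
    of ``context_selection`` atoms (selection atoms always occlude each
    other).  Default 960 points per sphere keeps the quadrature error of a
    single sphere below 0.5%."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    if np.any(radii <= 0):
        raise ValueError("non-positive atom radius")
    if n_points < 96:
        raise ValueError("n_points must be >= 96")
    n = coords.shape[0]
    sel = np.arange(n) if selection is None else np.asarray(selection, dtype=int)
    ctx = sel if context_selection is None else np.union1d(
        sel, np.asarray(context_selection, dtype=int))

    pts = sphere_points(n_points)
    ctx_coords = coords[ctx]
    ctx_radii = radii[ctx] + probe_radius
    tree = cKDTree(ctx_coords)
    max_r = ctx_radii.max()
    areas = np.empty(sel.size)
    for k, i in enumerate(sel):
        ri = radii[i] + probe_radius
        surface = coords[i] + ri * pts
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if ctx[j] != i]
        if neigh:
            d = np.linalg.norm(surface[:, None, :] - ctx_coords[neigh][None], axis=2)
            buried = (d < ctx_radii[neigh][None]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[k] = 4.0 * np.pi * ri * ri * frac
    return areas


def water_burial(traj: Trajectory, water: Residue, probe_radius: float = 1.4,
                 n_points: int = 960) -> GeometrySeries:
    """Solvent-exposure fraction of one water molecule in the full complex:
    SASA(water in complex) / SASA(isolated water).  Values below 0.10 mark
    a buried interface water."""
    top = traj.topology
    widx = np.asarray(water.atom_indices, dtype=int)
    radii = atom_radii(top.elements)
    out = np.empty(traj.n_snapshots)
    everything = np.arange(top.n_atoms)
    for si in range(traj.n_snapshots):
        xyz = traj.coords[si]
        in_complex = sasa(xyz, radii, widx, everything, probe_radius, n_points).sum()
        alone = sasa(xyz[widx], radii[widx], None, None, probe_radius,
                     n_points).sum()
        out[si] = in_complex / alone if alone > 0 else 0.0
    return GeometrySeries(f"exposure({water.chain_id}:{water.number})",
                          "dimensionless", out)


def buried_waters(traj: Trajectory, snapshot: int = 0, threshold: float = 0.10,
                  probe_radius: float = 1.4, n_points: int = 960
                  ) -> list[Residue]:
    """Waters with solvent exposure below ``threshold`` in one snapshot."""
    out = []
    for w in traj.topology.residues_of_class(T.WATER):
        frame = Trajectory(traj.topology, traj.coords[snapshot][None],
                           dt_ps=traj.dt_ps)
        if water_burial(frame, w, probe_radius, n_points).values[0] < threshold:
            out.append(w)
    return out


def occluded_area(traj: Trajectory, group_a: np.ndarray, group_b: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 960
                  ) -> GeometrySeries:
    """Contact area between two groups inaccessible to the probe.

    Per snapshot, with only the two groups present:
    ([SASA(A alone) - SASA(A in A+B)] + [SASA(B alone) - SASA(B in A+B)]) / 2.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("occluded_area groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("occluded_area groups overlap")
    top = traj.topology
    radii = atom_radii(top.elements)
    both = np.concatenate([a, b])
    out = np.empty(traj.n_snapshots)
    for si in range(traj.n_snapshots):
        xyz = traj.coords[si]
        a_alone = sasa(xyz[a], radii[a], None, None, probe_radius, n_points).sum()
        b_alone = sasa(xyz[b], radii[b], None, None, probe_radius, n_points).sum()
        pair = sasa(xyz[both], radii[both], None, None, probe_radius, n_points)
        a_pair = pair[: a.size].sum()
        b_pair = pair[a.size:].sum()
        out[si] = max(0.0, ((a_alone - a_pair) + (b_alone - b_pair)) / 2.0)
    return GeometrySeries("occluded_area", "angstrom2", out)
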