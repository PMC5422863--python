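"""Topology and trajectory containers for protein-DNA-water complexes.

A :class:`Topology` holds the static chemistry of the system — atoms grouped
into residues, residue classes (protein / dna / water / ion / other) and
hydrogen-bond donor/acceptor annotations.  A :class:`Trajectory` is an
ordered stack of coordinate snapshots over one topology with a fixed
snapshot spacing in picoseconds (the simulations this package targets save
one frame every 2 ps, 5000 frames per run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import templates as T


@dataclass
class AtomRecord:
    """One atom as read from (or destined for) a PDB ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    residue_number: int
    chain_id: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,):
            raise ValueError("coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name: str
    number: int
    chain_id: str
    atom_indices: np.ndarray
    res_class: str = T.OTHER

    def __len__(self) -> int:
        return len(self.atom_indices)


@dataclass
class Donor:
    """A donor heavy atom with its attached hydrogens (may be empty for
    crystal structures; detection then runs in heavy-atom mode)."""

    heavy: int
    hydrogens: tuple[int, ...] = ()


class Topology:
    """Atoms, residues, classes and donor/acceptor annotations."""

    def __init__(self, atoms: list[AtomRecord]):
        if not atoms:
            raise ValueError("empty topology")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials within a model")
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.elements = np.array([a.element.upper() for a in atoms], dtype=object)
        self.serials = np.array(serials, dtype=int)
        self.chain_ids = np.array([a.chain_id for a in atoms], dtype=object)
        self.res_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.res_numbers = np.array([a.residue_number for a in atoms], dtype=int)

        # contiguous residue grouping in file order
        self.residues: list[Residue] = []
        self.residue_index = np.empty(len(atoms), dtype=int)
        key = None
        start = 0
        for i, a in enumerate(atoms):
            k = (a.chain_id, a.residue_number, a.residue_name)
            if k != key:
                if key is not None:
                    self._close_residue(atoms, start, i)
                key, start = k, i
        self._close_residue(atoms, start, len(atoms))
        for ri, res in enumerate(self.residues):
            self.residue_index[res.atom_indices] = ri

        self.donors: list[Donor] = []
        self.acceptors: np.ndarray = np.empty(0, dtype=int)

    def _close_residue(self, atoms: list[AtomRecord], start: int, stop: int) -> None:
        a = atoms[start]
        self.residues.append(
            Residue(a.residue_name, a.residue_number, a.chain_id,
                    np.arange(start, stop)))

    # -- convenience ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def residue_classes(self) -> np.ndarray:
        return np.array([r.res_class for r in self.residues], dtype=object)

    @property
    def atom_classes(self) -> np.ndarray:
        return self.residue_classes[self.residue_index]

    def find_residue(self, chain_id: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.number == number:
                return r
        raise KeyError(f"no residue {chain_id}:{number}")

    def atom_in_residue(self, res: Residue, name: str) -> int:
        for i in res.atom_indices:
            if self.names[i] == name:
                return int(i)
        raise KeyError(f"no atom {name!r} in {res.chain_id}:{res.number}:{res.name}")

    def atom_index(self, chain_id: str, resnum: int, name: str) -> int:
        return self.atom_in_residue(self.find_residue(chain_id, resnum), name)

    def atom_label(self, i: int) -> str:
        ri = self.residue_index[i]
        r = self.residues[ri]
        return f"{r.chain_id}:{r.number}:{r.name}:{self.names[i]}"

    def residues_of_class(self, cls: str) -> list[Residue]:
        return [r for r in self.residues if r.res_class == cls]


@dataclass
class Trajectory:
    """Coordinate snapshots (n_snapshots, n_atoms, 3) over one topology."""

    topology: Topology
    coords: np.ndarray
    dt_ps: float = 2.0
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_snapshots, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"snapshot atom count {self.coords.shape[1]} does not match "
                f"topology size {self.topology.n_atoms}")
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")

    @property
    def n_snapshots(self) -> int:
        return self.coords.shape[0]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_snapshots) * self.dt_ps

    def __len__(self) -> int:
        return self.n_snapshots


def classify_residues(topology: Topology,
                      extra_templates: dict[str, T.ResidueTemplate] | None = None,
                      coords: np.ndarray | None = None) -> Topology:
    """Assign residue classes and populate donor/acceptor annotations in place.

    Donor hydrogens are located geometrically: a hydrogen belongs to a donor
    heavy atom if it sits within 1.2 Angstrom of it in ``coords`` (defaults to
    the atom coordinates recorded at build time, which the PDB reader stores
    as the first snapshot; pass them explicitly when classifying a bare
    topology).  Unknown residue names are classed ``other`` with a warning.
    """
    table = T.builtin_templates()
    if extra_templates:
        table.update(extra_templates)

    donors: list[Donor] = []
    acceptors: list[int] = []
    for res in topology.residues:
        tmpl = table.get(res.name.upper())
        if tmpl is None:
            res.res_class = T.OTHER
            warnings.warn(f"unknown residue {res.name!r} "
                          f"({res.chain_id}:{res.number}) classed 'other'")
            continue
        res.res_class = tmpl.res_class
        names_here = {topology.names[i]: int(i) for i in res.atom_indices}
        missing = [a for a in tmpl.required if a not in names_here]
        if missing:
            warnings.warn(f"residue {res.chain_id}:{res.number}:{res.name} "
                          f"missing template atoms {missing}; best-effort annotation")
        h_idx = [i for i in res.atom_indices if topology.elements[i] == "H"]
        for dname in tmpl.donors:
            if dname not in names_here:
                continue
            heavy = names_here[dname]
            hyd: list[int] = []
            if coords is not None and h_idx:
                dpos = coords[heavy]
                for hi in h_idx:
                    if np.linalg.norm(coords[hi] - dpos) <= 1.2:
                        hyd.append(int(hi))
            donors.append(Donor(heavy, tuple(hyd)))
        for aname in tmpl.acceptors:
            if aname in names_here:
                acceptors.append(names_here[aname])
    topology.donors = donors
    topology.acceptors = np.array(sorted(set(acceptors)), dtype=int)
    topology.__dict__.pop("_hbond_arrays", None)  # invalidate detector cache
    return topology
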