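"""Reading and writing single- and multi-model PDB files.

Parsing is delegated to gemmi; this module validates the result into the
package's :class:`~fpgtraj.topology.Topology` / ``Trajectory`` containers:
one trajectory snapshot per MODEL record (a single snapshot when the file
has none), consistent atom counts across models enforced, alternate
locations collapsed to the highest-occupancy conformer (ties prefer 'A'),
and elements inferred from atom names when the element column is blank.
"""

from __future__ import annotations

import os
import warnings

import gemmi
import numpy as np

from .topology import AtomRecord, Topology, Trajectory, classify_residues

_TWO_LETTER = {"ZN", "NA", "MG", "CL", "CA", "FE", "MN", "CU", "NI", "BR",
               "SE", "CD", "HG", "CO", "LI"}


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """PDB v3 element inference from the atom-name column."""
    name = atom_name.strip()
    if not name:
        return ""
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in "Hh" and residue_name.upper() not in _TWO_LETTER:
        return "H"
    two = stripped[:2].upper()
    # two-letter element only when the residue name confirms it (ions)
    if two in _TWO_LETTER and residue_name.upper() == two:
        return two
    return stripped[0].upper()


def _looks_like_text(source) -> bool:
    return isinstance(source, str) and "\n" in source


def _prevalidate(text: str) -> None:
    """Cheap scan of coordinate fields so parse failures carry line numbers."""
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi]
                try:
                    float(fld)
                except ValueError:
                    raise ValueError(
                        f"unparseable coordinate field {fld!r} on line {ln}")


def read_pdb(source, classify: bool = True,
             extra_templates=None) -> tuple[Topology, Trajectory]:
    """Read a PDB file or PDB-format text into a topology and trajectory.

    Returns one snapshot per MODEL record (a single snapshot for files
    without MODEL records).  Raises ``ValueError`` for inconsistent atom
    counts across models (naming the model index) or unparseable coordinate
    fields (naming the line number).
    """
    if _looks_like_text(source):
        text = source
        label = ""
    else:
        with open(os.fspath(source)) as fh:
            text = fh.read()
        label = os.path.splitext(os.path.basename(os.fspath(source)))[0]
    _prevalidate(text)
    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise ValueError("PDB input contains no models")

    records, coords0, key_order = _model_atoms(structure[0])
    snapshots = [coords0]
    for mi in range(1, len(structure)):
        _, coords, keys = _model_atoms(structure[mi])
        if keys != key_order:
            raise ValueError(
                f"model {mi + 1} has {len(keys)} atoms inconsistent with "
                f"model 1 ({len(key_order)} atoms)")
        snapshots.append(coords)

    topology = Topology(records)
    trajectory = Trajectory(topology, np.stack(snapshots), label=label)
    if classify:
        classify_residues(topology, extra_templates, coords=snapshots[0])
    return topology, trajectory


def _model_atoms(model: gemmi.Model):
    """Flatten one gemmi model, collapsing alt-locs to the preferred conformer."""
    records: list[AtomRecord] = []
    coords: list[list[float]] = []
    keys: list[tuple] = []
    serial = 0
    n_discarded = 0
    for chain in model:
        for residue in chain:
            chosen: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = chosen.get(atom.name)
                if prev is None or _altloc_rank(atom) > _altloc_rank(prev):
                    if prev is not None:
                        n_discarded += 1
                    chosen[atom.name] = atom
                elif prev is not None:
                    n_discarded += 1
            for atom in residue:
                if chosen.get(atom.name) is not atom:
                    continue
                serial += 1
                element = "H" if atom.element.is_hydrogen \
                    else atom.element.name.upper()
                if element in ("", "X"):
                    element = infer_element(atom.name, residue.name)
                records.append(AtomRecord(
                    serial=serial, name=atom.name, element=element,
                    alt_loc=(atom.altloc or ""), residue_name=residue.name,
                    residue_number=residue.seqid.num, chain_id=chain.name,
                    coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                keys.append((chain.name, residue.seqid.num, residue.name, atom.name))
    if n_discarded:
        warnings.warn(f"discarded {n_discarded} alternate-location atom records "
                      f"(kept highest occupancy, ties prefer 'A')")
    return records, np.asarray(coords, dtype=float), keys


def _altloc_rank(atom: gemmi.Atom) -> tuple:
    # higher occupancy wins; on ties, altloc 'A' (or blank) wins
    alt = atom.altloc or ""
    return (atom.occ, alt in ("", "A"), -ord(alt) if alt else 0)


def write_pdb(topology: Topology, trajectory: Trajectory,
              destination=None, model_records_for_single: bool = False) -> str:
    """Format a topology + trajectory as (multi-model) PDB text.

    Files with more than one snapshot always get MODEL/ENDMDL pairs; for a
    single snapshot the bare-record dialect is the default.  Coordinates
    that overflow the fixed 8.3 columns raise ``ValueError``.
    """
    if trajectory.n_snapshots == 0:
        raise ValueError("empty trajectory")
    if trajectory.coords.shape[1] != topology.n_atoms:
        raise ValueError("trajectory does not match topology")
    if np.any(trajectory.coords >= 10000.0) or np.any(trajectory.coords <= -1000.0):
        raise ValueError("coordinates overflow fixed PDB columns")
    numbers = [r.number for r in topology.residues]
    if max(numbers) > 9999 or min(numbers) < -999:
        raise ValueError("residue numbers overflow fixed PDB columns")

    use_models = trajectory.n_snapshots > 1 or model_records_for_single
    lines: list[str] = []
    for si in range(trajectory.n_snapshots):
        if use_models:
            lines.append(f"MODEL     {si + 1:4d}")
        xyz = trajectory.coords[si]
        prev_chain = None
        for i in range(topology.n_atoms):
            res = topology.residues[topology.residue_index[i]]
            if prev_chain is not None and res.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = res.chain_id
            record = "ATOM  " if res.res_class in ("protein", "dna") else "HETATM"
            name = topology.names[i]
            # PDB alignment: element symbols of one letter start in column 14
            fname = f" {name:<3s}" if len(name) < 4 and len(topology.elements[i]) == 1 \
                else f"{name:<4s}"
            lines.append(
                f"{record}{topology.serials[i] % 100000:5d} {fname}"
                f"{'':1s}{res.name:<4s}{res.chain_id[:1] or 'A':1s}"
                f"{res.number:4d}    "
                f"{xyz[i, 0]:8.3f}{xyz[i, 1]:8.3f}{xyz[i, 2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          "
                f"{topology.elements[i]:>2s}")
        lines.append("TER")
        if use_models:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        with open(os.fspath(destination), "w") as fh:
            fh.write(text)
    return text
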