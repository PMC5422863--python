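"""Per-residue chemistry templates: residue classes, hydrogen-bond donors and acceptors.

The tables cover the standard amino acids (plus the neutral carboxyl variant
GLH used for a protonated Glu2), the four deoxynucleotides with legacy
one-letter names, the 8-oxoguanine lesion (8OG / OXG), waters and common
monatomic ions.  Users can extend or override entries for modified residues
(carbacyclic lesions, neutral N-terminal proline, ...) either
programmatically or from a plain-text template file.
"""

from __future__ import annotations

from dataclasses import dataclass, field


PROTEIN = "protein"
DNA = "dna"
WATER = "water"
ION = "ion"
OTHER = "other"

RESIDUE_CLASSES = (PROTEIN, DNA, WATER, ION, OTHER)


@dataclass
class ResidueTemplate:
    """Donor/acceptor annotation for one residue type.

    ``donors`` lists donor *heavy* atoms; attached hydrogens are discovered
    geometrically (<= 1.2 Angstrom) when the model includes them, so the same
    template serves both hydrogen-bearing MD snapshots and crystal structures
    without hydrogens.
    """

    name: str
    res_class: str
    donors: tuple[str, ...] = ()
    acceptors: tuple[str, ...] = ()
    # heavy atoms the template considers essential; used only for warnings
    required: tuple[str, ...] = ()


_BB_DONORS = ("N",)
_BB_ACCEPTORS = ("O", "OXT")

# Phosphate and sugar oxygens shared by every nucleotide.
_NA_BACKBONE_ACC = ("OP1", "OP2", "O1P", "O2P", "O3'", "O4'", "O5'")


def _aa(name: str, donors: tuple[str, ...] = (), acceptors: tuple[str, ...] = (),
        required: tuple[str, ...] = (), backbone_nh: bool = True) -> ResidueTemplate:
    d = (_BB_DONORS if backbone_nh else ()) + donors
    return ResidueTemplate(name, PROTEIN, d, _BB_ACCEPTORS + acceptors, required)


def _nt(name: str, donors: tuple[str, ...], acceptors: tuple[str, ...],
        required: tuple[str, ...] = ()) -> ResidueTemplate:
    return ResidueTemplate(name, DNA, donors, acceptors + _NA_BACKBONE_ACC, required)


_TEMPLATES: dict[str, ResidueTemplate] = {}


def _register(t: ResidueTemplate) -> None:
    _TEMPLATES[t.name] = t


for _t in [
    _aa("ALA"), _aa("GLY"), _aa("VAL"), _aa("LEU"), _aa("ILE"),
    _aa("PHE"), _aa("MET", acceptors=("SD",)),
    _aa("PRO", backbone_nh=False),
    _aa("SER", donors=("OG",), acceptors=("OG",), required=("OG",)),
    _aa("THR", donors=("OG1",), acceptors=("OG1",), required=("OG1",)),
    _aa("CYS", donors=("SG",), acceptors=("SG",)),
    _aa("TYR", donors=("OH",), acceptors=("OH",)),
    _aa("TRP", donors=("NE1",)),
    _aa("ASN", donors=("ND2",), acceptors=("OD1",), required=("OD1", "ND2")),
    _aa("GLN", donors=("NE2",), acceptors=("OE1",), required=("OE1", "NE2")),
    _aa("ASP", acceptors=("OD1", "OD2"), required=("OD1", "OD2")),
    _aa("GLU", acceptors=("OE1", "OE2"), required=("OE1", "OE2")),
    # protonated glutamate side chain: OE2 carries the proton and can donate
    _aa("GLH", donors=("OE2",), acceptors=("OE1", "OE2"), required=("OE1", "OE2")),
    _aa("ASH", donors=("OD2",), acceptors=("OD1", "OD2")),
    _aa("LYS", donors=("NZ",), required=("NZ",)),
    _aa("ARG", donors=("NE", "NH1", "NH2"), required=("NE", "NH1", "NH2")),
    _aa("HIS", donors=("ND1", "NE2"), acceptors=("ND1", "NE2")),
    _aa("HID", donors=("ND1",), acceptors=("NE2",)),
    _aa("HIE", donors=("NE2",), acceptors=("ND1",)),
    _aa("HIP", donors=("ND1", "NE2")),
]:
    _register(_t)

for _names, _don, _acc in [
    (("DA", "A", "ADE"), ("N6",), ("N1", "N3", "N7")),
    (("DC", "C", "CYT"), ("N4",), ("O2", "N3")),
    (("DG", "G", "GUA"), ("N1", "N2"), ("O6", "N3", "N7")),
    (("DT", "T", "THY"), ("N3",), ("O2", "O4")),
    # 8-oxoguanine: N7 is protonated (pyrrole-like), C8 carries the extra
    # carbonyl oxygen O8; both faces of the base can hydrogen bond.
    (("8OG", "OXG", "8OGU"), ("N1", "N2", "N7"), ("O6", "O8", "N3")),
]:
    for _n in _names:
        _register(_nt(_n, _don, _acc))

for _w in ("HOH", "WAT", "H2O", "TIP3", "SOL", "DOD"):
    _register(ResidueTemplate(_w, WATER, donors=("O", "OW"), acceptors=("O", "OW"),
                              required=("O",)))

for _i in ("ZN", "NA", "K", "MG", "CA", "CL", "MN", "FE", "CU", "NI", "BR", "IOD"):
    _register(ResidueTemplate(_i, ION))


def builtin_templates() -> dict[str, ResidueTemplate]:
    """A copy of the built-in template table (safe to mutate)."""
    return dict(_TEMPLATES)


def parse_template_text(text: str) -> dict[str, ResidueTemplate]:
    """Parse a plain-text template table.

    One residue per line::

        8OG  class=dna  donors=N1,N2,N7  acceptors=O6,O8,N3

    Blank lines and ``#`` comments are ignored.  Returned entries can be
    merged over :func:`builtin_templates` to extend or override it.
    """
    out: dict[str, ResidueTemplate] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        name = parts[0].upper()
        cls = OTHER
        donors: tuple[str, ...] = ()
        acceptors: tuple[str, ...] = ()
        for p in parts[1:]:
            if "=" not in p:
                raise ValueError(f"template line {ln}: expected key=value, got {p!r}")
            key, val = p.split("=", 1)
            if key == "class":
                if val not in RESIDUE_CLASSES:
                    raise ValueError(f"template line {ln}: unknown class {val!r}")
                cls = val
            elif key == "donors":
                donors = tuple(v for v in val.split(",") if v)
            elif key == "acceptors":
                acceptors = tuple(v for v in val.split(",") if v)
            else:
                raise ValueError(f"template line {ln}: unknown key {key!r}")
        out[name] = ResidueTemplate(name, cls, donors, acceptors)
    return out


#: van der Waals radii (Angstrom) used for surface-area calculations.
#: Bondi (1964) values with the common PDB-element fallbacks.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "ZN": 1.39, "MG": 1.73,
    "NA": 2.27, "K": 2.75, "CA": 2.31, "FE": 1.52, "MN": 1.61, "CU": 1.40,
}
VDW_DEFAULT = 1.70

#: atomic masses for mass-weighted geometry (standard atomic weights)
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "ZN": 65.38, "MG": 24.305, "NA": 22.990, "K": 39.098,
    "CA": 40.078, "CL": 35.45, "FE": 55.845, "MN": 54.938,
}
MASS_DEFAULT = 12.011
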