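"""Cα-chain structures and PDB input/output.

The whole package works on a light container, :class:`CaStructure`: an
ordered list of residues, each with a Cα coordinate and (optionally) the
residue's heavy atoms.  Real structures come from PDB files via gemmi;
synthetic fixtures are built directly.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

log = logging.getLogger(__name__)

#: The 20 standard amino acids, three-letter PDB names -> one-letter codes.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = tuple(sorted(AA3_TO_1))
AA_INDEX = {name: i for i, name in enumerate(STANDARD_AA)}

#: Common nonstandard residues mapped onto their standard parent (editable).
NONSTANDARD_MAP = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
}

#: Bondi van der Waals radii (Å) by element; used for native-contact rules.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70


def normalize_resname(name: str) -> str | None:
    """Map a PDB residue name to one of the 20 standard names, or None."""
    name = name.strip().upper()
    if name in AA3_TO_1:
        return name
    return NONSTANDARD_MAP.get(name)


@dataclass
class Residue:
    name: str                      # standard 3-letter name
    ca: np.ndarray                 # (3,) Cα coordinate, Å
    heavy_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)
    # (element symbol, coordinate); includes the Cα when read from a PDB


@dataclass
class CaStructure:
    """An ordered Cα chain, optionally carrying heavy atoms per residue.

    ``synthetic`` marks fixtures allowed to relax the physical
    consecutive-Cα bond-length window of [2.8, 4.2] Å.
    """

    residues: list[Residue]
    name: str = ""
    synthetic: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a CaStructure needs at least 2 residues")
        if not self.synthetic:
            d = np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)
            if ((d < 2.8) | (d > 4.2)).any():
                bad = int(np.argmax((d < 2.8) | (d > 4.2)))
                raise ValueError(
                    f"{self.name or 'chain'}: consecutive Ca-Ca distance "
                    f"{d[bad]:.2f} A at residue {bad + 1} outside [2.8, 4.2]"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.asarray([r.ca for r in self.residues], dtype=float)

    @property
    def resnames(self) -> list[str]:
        return [r.name for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(AA3_TO_1[r.name] for r in self.residues)

    @property
    def has_heavy_atoms(self) -> bool:
        return all(len(r.heavy_atoms) > 0 for r in self.residues)


def read_pdb(path, chain: str | None = None,
             residue_range: tuple[int, int] | None = None,
             name: str | None = None) -> CaStructure:
    """Read one chain of a PDB file into a CaStructure.

    altLocs are resolved to the highest occupancy; nonstandard residues are
    remapped where possible, otherwise skipped with a warning.  ``residue_range``
    is an inclusive (start, end) window of author residue numbers, for picking
    e.g. one domain out of a longer deposited chain.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = model[chain]
    residues: list[Residue] = []
    for res in ch:
        if residue_range is not None:
            num = res.seqid.num
            if num < residue_range[0] or num > residue_range[1]:
                continue
        rname = normalize_resname(res.name)
        if rname is None:
            if res.is_amino_acid():
                warnings.warn(f"skipping unknown residue {res.name}")
            continue
        ca = res.find_atom("CA", "*")
        if ca is None:
            warnings.warn(f"residue {res.name} {res.seqid.num} lacks CA; skipped")
            continue
        heavy = [(a.element.name.upper(), np.array(a.pos.tolist()))
                 for a in res if not a.is_hydrogen()]
        residues.append(Residue(rname, np.array(ca.pos.tolist()), heavy))
    return CaStructure(residues, name=name or st.name)


def write_pdb(structure: CaStructure, path) -> None:
    """Write a CaStructure (Cα + any pseudo side-chain atoms) as a PDB file."""
    st = gemmi.Structure()
    st.name = structure.name or "SYNTH"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    serial = 1
    for i, res in enumerate(structure.residues, start=1):
        r = gemmi.Residue()
        r.name = res.name
        r.seqid = gemmi.SeqId(i, " ")
        atoms = res.heavy_atoms or [("C", res.ca)]
        names_seen: set[str] = set()
        for j, (elem, pos) in enumerate(atoms):
            a = gemmi.Atom()
            if np.allclose(pos, res.ca):
                a.name = "CA"
            else:
                a.name = f"CB" if "CB" not in names_seen else f"C{j}"
            names_seen.add(a.name)
            a.element = gemmi.Element(elem)
            a.pos = gemmi.Position(*pos)
            a.occ = 1.0
            a.serial = serial
            serial += 1
            r.add_atom(a)
        ch.add_residue(r)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
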