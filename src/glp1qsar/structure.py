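"""Receptor-peptide complex structures: PDB I/O and chemical annotation.

Complexes are read from standard PDB text (via Biopython) and partitioned
into receptor chains and one peptide chain. Each atom is assigned a
polarity class used by the interaction detectors and the solvation model:

* ``polar_hydrogen``   - H bonded to N/O/S
* ``apolar_hydrogen``  - any other H
* ``apolar_carbon``    - C with no bonded N/O/S
* ``polar_heavy``      - N, O, S, halogens, and carbons bonded to them
* ``charged``          - member of a formally ionized group

Aromatic rings and formal charge centers are enumerated from a residue
template table shipped as package data (canonical amino acids plus the
noncanonical residues of this series: AIB, biphenylalanine, fluorinated
and Cα-methylated phenylalanines) and extensible at run time via
:func:`register_residue_template`.

Covalent bonds are inferred geometrically (distance below the sum of
covalent radii plus 0.45 Å), so structures with or without explicit
hydrogens are both supported.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "AtomRecord",
    "Ring",
    "ChargeCenter",
    "ComplexStructure",
    "read_structure",
    "write_pdb",
    "register_residue_template",
    "known_residues",
]

SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "S", "F", "CL", "BR"}

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "F": 0.57, "CL": 1.02, "BR": 1.20,
}
_BOND_SLACK = 0.45  # Å added to the covalent-radii sum

_RING_PLANARITY_TOL = 0.3  # Å max out-of-plane deviation


def _load_templates() -> dict:
    with resources.files("glp1qsar.data").joinpath(
        "residue_templates.json"
    ).open("r") as fh:
        return json.load(fh)


_TEMPLATES: dict[str, dict] = _load_templates()


def register_residue_template(
    name: str,
    rings: Sequence[Sequence[str]] = (),
    cation_groups: Sequence[Sequence[str]] = (),
    anion_groups: Sequence[Sequence[str]] = (),
) -> None:
    """Register (or replace) a residue template for nonstandard residues."""
    _TEMPLATES[name.upper()] = {
        "rings": [list(r) for r in rings],
        "cation_groups": [list(g) for g in cation_groups],
        "anion_groups": [list(g) for g in anion_groups],
    }


def known_residues() -> frozenset[str]:
    return frozenset(_TEMPLATES)


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    xyz: np.ndarray
    polarity_class: str | None = None
    charge_group: str | None = None  # "cation" | "anion" | "aromatic_ring_member"

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.serial}: coordinates must be finite 3-vectors")
        object.__setattr__(self, "xyz", xyz)
        if self.element.upper() not in SUPPORTED_ELEMENTS:
            raise ValueError(
                f"atom {self.serial} ({self.name}): unsupported element "
                f"{self.element!r}"
            )


@dataclass(frozen=True)
class Ring:
    """An aromatic ring: member atom indices, centroid and unit normal."""

    atom_indices: tuple[int, ...]
    chain_id: str
    centroid: np.ndarray
    normal: np.ndarray


@dataclass(frozen=True)
class ChargeCenter:
    """A formally charged group, collapsed to its geometric center."""

    sign: int  # +1 cation, -1 anion
    atom_indices: tuple[int, ...]
    chain_id: str
    center: np.ndarray


@dataclass(frozen=True)
class ComplexStructure:
    atoms: tuple[AtomRecord, ...]
    receptor_chains: frozenset[str]
    peptide_chain: str
    rings: tuple[Ring, ...] = ()
    charge_centers: tuple[ChargeCenter, ...] = ()
    bonds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.receptor_chains or not self.peptide_chain:
            raise ValueError("both receptor and peptide chains are required")
        if self.peptide_chain in self.receptor_chains:
            raise ValueError("receptor and peptide chain sets must be disjoint")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def is_peptide(self, atom: AtomRecord) -> bool:
        return atom.chain_id == self.peptide_chain

    @property
    def peptide_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if self.is_peptide(a)], dtype=int
        )

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if not self.is_peptide(a)], dtype=int
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "ComplexStructure":
        """Rigid-body transform x -> R x + t applied to every geometric field."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        atoms = tuple(
            replace(a, xyz=rotation @ a.xyz + translation) for a in self.atoms
        )
        rings = tuple(
            Ring(r.atom_indices, r.chain_id,
                 rotation @ r.centroid + translation, rotation @ r.normal)
            for r in self.rings
        )
        centers = tuple(
            ChargeCenter(c.sign, c.atom_indices, c.chain_id,
                         rotation @ c.center + translation)
            for c in self.charge_centers
        )
        return ComplexStructure(atoms, self.receptor_chains, self.peptide_chain,
                                rings, centers, self.bonds)

    def swapped_labels(self) -> "ComplexStructure":
        """Relabel a two-chain complex with the roles of the chains exchanged."""
        if len(self.receptor_chains) != 1:
            raise ValueError("label swap requires a single receptor chain")
        (rec,) = self.receptor_chains
        return ComplexStructure(self.atoms, frozenset({self.peptide_chain}),
                                rec, self.rings, self.charge_centers, self.bonds)


# ---------------------------------------------------------------------------
# Parsing and annotation
# ---------------------------------------------------------------------------

def _check_coordinate_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(
                    f"unparseable coordinate fields on line {lineno}: {line!r}"
                ) from None


def infer_bonds(coords: np.ndarray, elements: Sequence[str]) -> list[tuple[int, int]]:
    """Geometric covalent-bond inference from interatomic distances."""
    n = len(elements)
    radii = np.array([_COVALENT_RADII[e.upper()] for e in elements])
    bonds: list[tuple[int, int]] = []
    if n < 2:
        return bonds
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cutoff = radii[:, None] + radii[None, :] + _BOND_SLACK
    ii, jj = np.where((d > 1e-6) & (d < cutoff))
    for i, j in zip(ii, jj):
        if i < j:
            bonds.append((int(i), int(j)))
    return bonds


def _classify_atoms(
    atoms: list[AtomRecord], bonds: list[tuple[int, int]]
) -> list[AtomRecord]:
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)

    out = []
    for i, atom in enumerate(atoms):
        elem = atom.element.upper()
        nbr_elems = {atoms[j].element.upper() for j in neighbors[i]}
        if elem == "H":
            cls = ("polar_hydrogen" if nbr_elems & {"N", "O", "S"}
                   else "apolar_hydrogen")
        elif elem == "C":
            cls = ("apolar_carbon" if not (nbr_elems & {"N", "O", "S"})
                   else "polar_heavy")
        else:
            cls = "polar_heavy"
        out.append(replace(atom, polarity_class=cls))
    return out


def _fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    max_dev = float(np.max(np.abs(centered @ normal)))
    return centroid, normal, max_dev


def _annotate_groups(
    atoms: list[AtomRecord],
) -> tuple[list[AtomRecord], list[Ring], list[ChargeCenter]]:
    # group atoms by (chain, residue number, residue name)
    by_residue: dict[tuple, list[int]] = {}
    for i, a in enumerate(atoms):
        by_residue.setdefault(
            (a.chain_id, a.residue_number, a.residue_name.upper()), []
        ).append(i)

    rings: list[Ring] = []
    centers: list[ChargeCenter] = []
    tagged = dict(enumerate(atoms))

    for (chain, resnum, resname), idxs in by_residue.items():
        tmpl = _TEMPLATES.get(resname)
        if tmpl is None:
            raise ValueError(
                f"no residue template for {resname!r} "
                f"(chain {chain}, residue {resnum}); register one with "
                "register_residue_template()"
            )
        name_to_idx = {atoms[i].name.upper(): i for i in idxs}
        for ring_names in tmpl.get("rings", ()):
            members = [name_to_idx[n] for n in ring_names if n in name_to_idx]
            if len(members) < 5:
                continue  # side chain absent or truncated
            coords = np.array([atoms[i].xyz for i in members])
            centroid, normal, dev = _fit_plane(coords)
            if dev > _RING_PLANARITY_TOL:
                raise ValueError(
                    f"ring {ring_names} of {resname} {chain}:{resnum} deviates "
                    f"{dev:.2f} Å from planarity (limit {_RING_PLANARITY_TOL})"
                )
            rings.append(Ring(tuple(members), chain, centroid, normal))
            for i in members:
                if tagged[i].charge_group is None:
                    tagged[i] = replace(tagged[i],
                                        charge_group="aromatic_ring_member")
        for sign, key in ((1, "cation_groups"), (-1, "anion_groups")):
            for group_names in tmpl.get(key, ()):
                members = [name_to_idx[n] for n in group_names
                           if n in name_to_idx]
                if len(members) != len(group_names):
                    continue
                center = np.mean([atoms[i].xyz for i in members], axis=0)
                centers.append(ChargeCenter(sign, tuple(members), chain, center))
                for i in members:
                    tagged[i] = replace(
                        tagged[i], charge_group="cation" if sign > 0 else "anion"
                    )
    return [tagged[i] for i in range(len(atoms))], rings, centers


def read_structure(
    pdb_text: str,
    peptide_chain: str,
    receptor_chains: Iterable[str] | None = None,
) -> ComplexStructure:
    """Parse PDB text into an annotated receptor-peptide complex."""
    _check_coordinate_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("complex", io.StringIO(pdb_text))[0]

    atoms: list[AtomRecord] = []
    chains_seen: list[str] = []
    for chain in model:
        chains_seen.append(chain.id)
        for residue in chain:
            for atom in residue:
                elem = atom.element.strip() or atom.get_name()[0]
                atoms.append(
                    AtomRecord(
                        serial=int(atom.serial_number),
                        name=atom.get_name(),
                        element=elem.upper(),
                        residue_name=residue.get_resname().strip(),
                        residue_number=int(residue.id[1]),
                        chain_id=chain.id,
                        xyz=np.array(atom.coord, dtype=float),
                    )
                )
    if len(set(chains_seen)) < 2:
        raise ValueError(
            f"a receptor-peptide complex needs at least two chains, "
            f"found {sorted(set(chains_seen))}"
        )
    if peptide_chain not in chains_seen:
        raise ValueError(f"peptide chain {peptide_chain!r} not present")
    if receptor_chains is None:
        receptor = frozenset(c for c in chains_seen if c != peptide_chain)
    else:
        receptor = frozenset(receptor_chains)

    coords = np.array([a.xyz for a in atoms])
    bonds = infer_bonds(coords, [a.element for a in atoms])
    atoms = _classify_atoms(atoms, bonds)
    atoms, rings, centers = _annotate_groups(atoms)
    return ComplexStructure(
        tuple(atoms), receptor, peptide_chain,
        tuple(rings), tuple(centers), tuple(bonds),
    )


def write_pdb(structure: ComplexStructure | Sequence[AtomRecord]) -> str:
    """Serialize atoms back to PDB text (ATOM records plus END)."""
    atoms = structure.atoms if isinstance(structure, ComplexStructure) else structure
    lines = []
    for a in atoms:
        x, y, z = a.xyz
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name:<4s} {a.residue_name:<3s} "
            f"{a.chain_id}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
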