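"""Binding-energy, solvation, packing and model-quality descriptors.

The eight binding-energy descriptors decompose a receptor-peptide binding
free-energy surrogate

    BE = BEpot - BS - BShydro,    BEpot = BEelec + BEvdw,   BS = BSelec + BSvdw

where every ``B*`` term is the corresponding quantity computed for the
complex minus the same quantity computed for the receptor and peptide
alone at frozen coordinates. Potential terms use a Coulomb sum (solute
dielectric 1) and a 6-12 Lennard-Jones sum with Lorentz-Berthelot
combining and a smooth 10->12 Å switch; for frozen coordinates the
three-way difference reduces identically to the cross-interface pair sum,
which is how it is evaluated (no cancellation of large intra-molecular
terms). Polar solvation uses a generalized-Born screening with the
molecular-surface solute radii; it is exact in the Born limit of a single
ion. Nonpolar solvation terms are proportional to solvent-accessible
surface area (total SASA for the solute-solvent vdw term, apolar SASA
for the hydrophobic term).

SASA is a Shrake-Rupley style numeric integral over a fixed golden-spiral
point set. All SASA-dependent quantities are evaluated in a canonical
molecular frame (principal axes with deterministic sign fixing) so that
descriptors are invariant under rigid-body transforms and atom
reordering; because the sphere directions are shared between the complex
and its frozen parts, a complex whose parts lie beyond all interaction
distances yields exactly zero for every binding descriptor.

The packing / model-quality scores are documented surrogates: Pack3D is a
negated distance-weighted count of non-bonded heavy-atom contacts within
6 Å; Pack1D is a negated count of sequence-local (same chain, residue
separation <= 2) or cross-chain non-bonded heavy-atom contacts within
4.5 Å; MQ is an affine combination of scaled packing density and a clash
count. Each Bind* score is complex minus parts.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import detect_all, interaction_summaries
from .params import EnergyModelParams
from .structure import AtomRecord, ComplexStructure

__all__ = [
    "DESCRIPTOR_NAMES",
    "DescriptorVector",
    "assign_charges",
    "pairwise_potential",
    "sasa",
    "solvation_terms",
    "binding_terms",
    "packing_scores",
    "descriptor_vector",
    "descriptor_table_from_pdbs",
]

#: Canonical descriptor order: 12 interaction, 6 quality/packing, 8 energy.
DESCRIPTOR_NAMES = (
    "HBondCount", "HydrophobicCount", "CationPiCount", "PiPiCount",
    "IonIonCount",
    "HBondEnergy", "HydrophobicEnergy", "CationPiEnergy", "PiPiEnergy",
    "IonIonEnergy",
    "InteractionCount", "InteractionEnergy",
    "CompMQ", "BindMQ", "CompPack1D", "BindPack1D", "CompPack3D",
    "BindPack3D",
    "BEpot", "BEelec", "BEvdw", "BS", "BSelec", "BSvdw", "BShydro", "BE",
)

CONTACT_DESCRIPTORS = DESCRIPTOR_NAMES[:12]
PACKING_DESCRIPTORS = DESCRIPTOR_NAMES[12:18]
ENERGY_DESCRIPTORS = DESCRIPTOR_NAMES[18:26]


@dataclass(frozen=True)
class DescriptorVector:
    """The 26 named interface descriptors of one complex."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in DESCRIPTOR_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"missing descriptors: {missing}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in DESCRIPTOR_NAMES})

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in DESCRIPTOR_NAMES])

    def validate_identities(self, atol: float = 1e-9) -> None:
        v = self.values
        checks = {
            "InteractionCount": sum(v[f"{k}Count"] for k in
                                    ("HBond", "Hydrophobic", "CationPi",
                                     "PiPi", "IonIon")),
            "InteractionEnergy": sum(v[f"{k}Energy"] for k in
                                     ("HBond", "Hydrophobic", "CationPi",
                                      "PiPi", "IonIon")),
            "BEpot": v["BEelec"] + v["BEvdw"],
            "BS": v["BSelec"] + v["BSvdw"],
            "BE": v["BEpot"] - v["BS"] - v["BShydro"],
        }
        for name, expected in checks.items():
            if abs(v[name] - expected) > atol:
                raise ValueError(
                    f"{name} identity violated: {v[name]} vs {expected}")


# ---------------------------------------------------------------------------
# Charges
# ---------------------------------------------------------------------------

def assign_charges(
    atoms: Sequence[AtomRecord],
    params: EnergyModelParams,
    charge_centers=(),
) -> np.ndarray:
    """Template partial charges: polar offsets plus unit formal charges.

    Polar hydrogens, N, O, S and polar carbons receive fixed offsets;
    apolar atoms are neutral. Each formally ionized group distributes a
    unit charge equally over its member atoms.
    """
    q = np.zeros(len(atoms))
    for i, a in enumerate(atoms):
        elem = a.element.upper()
        if a.polarity_class == "polar_hydrogen":
            q[i] = params.q_polar_hydrogen
        elif elem == "N":
            q[i] = params.q_nitrogen
        elif elem == "O":
            q[i] = params.q_oxygen
        elif elem == "S":
            q[i] = params.q_sulfur
        elif elem == "C" and a.polarity_class == "polar_heavy":
            q[i] = params.q_polar_carbon
    for center in charge_centers:
        share = center.sign / len(center.atom_indices)
        for i in center.atom_indices:
            q[i] += share
    return q


# ---------------------------------------------------------------------------
# Nonbonded potential
# ---------------------------------------------------------------------------

def _switch(r: np.ndarray, params: EnergyModelParams) -> np.ndarray:
    """Smoothstep from 1 at ``switch_on`` to 0 at ``cutoff``."""
    x = np.clip((r - params.switch_on) / (params.cutoff - params.switch_on),
                0.0, 1.0)
    return 1.0 - x * x * (3.0 - 2.0 * x)


def pairwise_potential(
    atoms_a: Sequence[AtomRecord],
    atoms_b: Sequence[AtomRecord],
    params: EnergyModelParams | None = None,
    charges_a: np.ndarray | None = None,
    charges_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """Cross-set (electrostatic, van der Waals) energies in kJ/mol.

    Atoms closer than 0.1 Å trigger a clash error rather than returning a
    huge repulsion.
    """
    params = params or EnergyModelParams.default()
    if charges_a is None:
        charges_a = assign_charges(atoms_a, params)
    if charges_b is None:
        charges_b = assign_charges(atoms_b, params)
    xa = np.array([a.xyz for a in atoms_a])
    xb = np.array([b.xyz for b in atoms_b])
    if len(xa) == 0 or len(xb) == 0:
        return 0.0, 0.0
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    if np.any(d < 0.1):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(
            f"atomic clash: atoms {atoms_a[i].serial} and {atoms_b[j].serial} "
            f"are {d[i, j]:.3f} Å apart"
        )
    sw = _switch(d, params)
    within = d < params.cutoff

    qq = np.outer(charges_a, charges_b)
    elec = float(np.sum(
        np.where(within,
                 params.coulomb_constant * qq / (params.dielectric_solute * d)
                 * sw, 0.0)
    ))

    sig_a = np.array([params.lj_sigma[a.element.upper()] for a in atoms_a])
    sig_b = np.array([params.lj_sigma[b.element.upper()] for b in atoms_b])
    eps_a = np.array([params.lj_epsilon[a.element.upper()] for a in atoms_a])
    eps_b = np.array([params.lj_epsilon[b.element.upper()] for b in atoms_b])
    sigma = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps = np.sqrt(np.outer(eps_a, eps_b))
    sr6 = (sigma / d) ** 6
    vdw = float(np.sum(
        np.where(within, 4.0 * eps * (sr6 * sr6 - sr6) * sw, 0.0)
    ))
    return elec, vdw


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic principal-axes frame (rotation R, translation t).

    ``x_canonical = R @ (x - t)``. The frame depends only on the point
    cloud geometry (not on point order), so quantities computed in it are
    invariant under rigid-body transforms of the input. Axis signs are
    fixed by the third (then fifth) moment of the projections; the frame
    is right-handed.
    """
    coords = np.asarray(coords, dtype=float)
    t = coords.mean(axis=0)
    centered = coords - t
    cov = centered.T @ centered / max(len(coords), 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    scale = float(np.max(np.abs(centered))) or 1.0
    for k in range(3):
        proj = centered @ axes[:, k]
        for moment in (3, 5):
            s = float(np.sum(proj ** moment))
            if abs(s) > 1e-9 * scale ** moment:
                if s < 0:
                    axes[:, k] = -axes[:, k]
                break
    # enforce a proper rotation
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes.T, t


def _sasa_raw(
    coords: np.ndarray, radii_ext: np.ndarray, n_points: int
) -> np.ndarray:
    """Per-atom SASA on already-oriented coordinates (extended radii)."""
    n = len(coords)
    pts = _sphere_points(n_points)
    areas = np.zeros(n)
    r2 = radii_ext ** 2
    for i in range(n):
        # only neighbors whose extended spheres can intersect atom i's
        d = np.linalg.norm(coords - coords[i], axis=1)
        nbr = np.where((d > 1e-9) & (d < radii_ext[i] + radii_ext))[0]
        surface = coords[i] + radii_ext[i] * pts
        if len(nbr):
            dist2 = np.sum(
                (surface[:, None, :] - coords[nbr][None, :, :]) ** 2, axis=-1
            )
            exposed = np.all(dist2 >= r2[nbr][None, :], axis=1)
            frac = float(np.count_nonzero(exposed)) / n_points
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r2[i] * frac
    return areas


def _radii(atoms: Sequence[AtomRecord], params: EnergyModelParams) -> np.ndarray:
    return np.array(
        [params.solute_radius(a.element, a.polarity_class) for a in atoms]
    )


def sasa(
    atoms: Sequence[AtomRecord],
    params: EnergyModelParams | None = None,
    n_points: int | None = None,
    canonicalize: bool = True,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas in Å²."""
    params = params or EnergyModelParams.default()
    n_points = n_points or params.sasa_points
    coords = np.array([a.xyz for a in atoms], dtype=float)
    if canonicalize and len(atoms) > 1:
        rot, t = canonical_frame(coords)
        coords = (coords - t) @ rot.T
    radii_ext = _radii(atoms, params) + params.probe_radius
    return _sasa_raw(coords, radii_ext, n_points)


# ---------------------------------------------------------------------------
# Solvation
# ---------------------------------------------------------------------------

def _born_polar(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    params: EnergyModelParams,
) -> float:
    """Generalized-Born polar solvation free energy in kJ/mol.

    Off-diagonal screening terms carry the nonbonded switch so that
    molecules beyond the cutoff do not interact through the solvent term.
    """
    if len(coords) == 0:
        return 0.0
    pref = -0.5 * params.coulomb_constant * (
        1.0 / params.dielectric_solute - 1.0 / params.dielectric_solvent
    )
    self_term = float(np.sum(charges ** 2 / born_radii))
    if len(coords) == 1:
        return pref * self_term
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    rr = np.outer(born_radii, born_radii)
    f_gb = np.sqrt(d2 + rr * np.exp(-d2 / (4.0 * rr)))
    qq = np.outer(charges, charges)
    d = np.sqrt(d2)
    off = np.where(
        (d > 1e-9) & (d < params.cutoff),
        qq / f_gb * _switch(d, params), 0.0,
    )
    return pref * (self_term + float(np.sum(off)))


def solvation_terms(
    atoms: Sequence[AtomRecord],
    params: EnergyModelParams | None = None,
    charges: np.ndarray | None = None,
    sasa_per_atom: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(polar, solute-solvent vdw, hydrophobic) solvation terms, kJ/mol."""
    params = params or EnergyModelParams.default()
    if charges is None:
        charges = assign_charges(atoms, params)
    coords = np.array([a.xyz for a in atoms], dtype=float)
    born_radii = _radii(atoms, params)
    polar = _born_polar(coords, charges, born_radii, params)
    if sasa_per_atom is None:
        sasa_per_atom = sasa(atoms, params)
    total = float(np.sum(sasa_per_atom))
    apolar_mask = np.array(
        [a.polarity_class in ("apolar_carbon", "apolar_hydrogen")
         for a in atoms]
    )
    apolar_area = float(np.sum(sasa_per_atom[apolar_mask]))
    return (polar, params.sasa_vdw_coeff * total,
            params.surface_tension * apolar_area)


# ---------------------------------------------------------------------------
# Binding decomposition
# ---------------------------------------------------------------------------

def _canonicalized(structure: ComplexStructure) -> ComplexStructure:
    coords = structure.coords()
    if len(coords) < 2:
        return structure
    rot, t = canonical_frame(coords)
    return structure.transformed(rot, -rot @ t)


def binding_terms(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> dict[str, float]:
    """The eight binding-energy descriptors of a complex.

    Every term is complex minus frozen parts; the potential terms are
    evaluated as the algebraically identical cross-interface sums.
    """
    params = params or EnergyModelParams.default()
    structure = _canonicalized(structure)
    atoms = structure.atoms
    charges = assign_charges(atoms, params, structure.charge_centers)
    pep = structure.peptide_indices
    rec = structure.receptor_indices
    atoms_r = [atoms[i] for i in rec]
    atoms_p = [atoms[i] for i in pep]

    be_elec, be_vdw = pairwise_potential(
        atoms_r, atoms_p, params, charges[rec], charges[pep]
    )

    radii_ext = _radii(atoms, params) + params.probe_radius
    coords = structure.coords()
    sasa_complex = _sasa_raw(coords, radii_ext, params.sasa_points)
    sasa_r = _sasa_raw(coords[rec], radii_ext[rec], params.sasa_points)
    sasa_p = _sasa_raw(coords[pep], radii_ext[pep], params.sasa_points)

    def solv(idx, sasa_part):
        part = [atoms[i] for i in idx]
        return solvation_terms(part, params, charges[idx], sasa_part)

    all_idx = np.arange(len(atoms))
    s_c = solv(all_idx, sasa_complex)
    s_r = solv(rec, sasa_r)
    s_p = solv(pep, sasa_p)
    bs_elec, bs_vdw, bs_hydro = (
        s_c[k] - s_r[k] - s_p[k] for k in range(3)
    )

    be_pot = be_elec + be_vdw
    bs = bs_elec + bs_vdw
    return {
        "BEpot": be_pot,
        "BEelec": be_elec,
        "BEvdw": be_vdw,
        "BS": bs,
        "BSelec": bs_elec,
        "BSvdw": bs_vdw,
        "BShydro": bs_hydro,
        "BE": be_pot - bs - bs_hydro,
    }


# ---------------------------------------------------------------------------
# Packing / model quality
# ---------------------------------------------------------------------------

_PACK3D_CUTOFF = 6.0
_PACK1D_CUTOFF = 4.5
_CLASH_DIST = 2.4
_MQ_PACK_SCALE = 0.1
_MQ_CLASH_WEIGHT = 0.5


def _heavy_contacts(atoms, bonds):
    """Non-bonded heavy-atom pairs with their distances."""
    heavy = [i for i, a in enumerate(atoms) if a.element.upper() != "H"]
    bonded = set(bonds) | {(j, i) for i, j in bonds}
    coords = np.array([atoms[i].xyz for i in heavy])
    out = []
    for ai in range(len(heavy)):
        for aj in range(ai + 1, len(heavy)):
            i, j = heavy[ai], heavy[aj]
            if (i, j) in bonded:
                continue
            d = float(np.linalg.norm(coords[ai] - coords[aj]))
            out.append((i, j, d))
    return out


def _pack_scores_for(atoms, bonds) -> tuple[float, float, float]:
    """(Pack1D, Pack3D, MQ) for one structure (or frozen part)."""
    contacts = _heavy_contacts(atoms, bonds)
    pack3d = 0.0
    pack1d = 0
    clashes = 0
    for i, j, d in contacts:
        if d <= _PACK3D_CUTOFF:
            pack3d -= 1.0 - d / _PACK3D_CUTOFF
        if d <= _PACK1D_CUTOFF:
            a, b = atoms[i], atoms[j]
            local = (a.chain_id != b.chain_id
                     or abs(a.residue_number - b.residue_number) <= 2)
            if local:
                pack1d += 1
        if d < _CLASH_DIST:
            clashes += 1
    mq = _MQ_PACK_SCALE * (-pack3d) - _MQ_CLASH_WEIGHT * clashes
    return -float(pack1d), pack3d, mq


def packing_scores(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> dict[str, float]:
    """The six quality/packing descriptors (Comp* and Bind* = Comp - parts)."""
    atoms = structure.atoms
    pep_set = set(structure.peptide_indices.tolist())

    def part(idx_set):
        idx = sorted(idx_set)
        remap = {i: k for k, i in enumerate(idx)}
        part_atoms = [atoms[i] for i in idx]
        part_bonds = [(remap[i], remap[j]) for i, j in structure.bonds
                      if i in idx_set and j in idx_set]
        return part_atoms, part_bonds

    comp1d, comp3d, comp_mq = _pack_scores_for(
        atoms, [tuple(b) for b in structure.bonds]
    )
    r_atoms, r_bonds = part(set(range(len(atoms))) - pep_set)
    p_atoms, p_bonds = part(pep_set)
    r1d, r3d, r_mq = _pack_scores_for(r_atoms, r_bonds)
    p1d, p3d, p_mq = _pack_scores_for(p_atoms, p_bonds)
    return {
        "CompMQ": comp_mq,
        "BindMQ": comp_mq - r_mq - p_mq,
        "CompPack1D": comp1d,
        "BindPack1D": comp1d - r1d - p1d,
        "CompPack3D": comp3d,
        "BindPack3D": comp3d - r3d - p3d,
    }


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def descriptor_vector(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> DescriptorVector:
    """All 26 interface descriptors of one complex, in canonical order."""
    params = params or EnergyModelParams.default()
    structure = _canonicalized(structure)
    values: dict[str, float] = {}
    values.update(interaction_summaries(detect_all(structure, params)))
    values.update(packing_scores(structure, params))
    values.update(binding_terms(structure, params))
    vec = DescriptorVector(values)
    vec.validate_identities()
    return vec


def descriptor_table_from_pdbs(
    pdb_texts: dict[str, str],
    peptide_chain: str,
    params: EnergyModelParams | None = None,
) -> pd.DataFrame:
    """Descriptor table (one row per complex id) from PDB text blocks."""
    from .structure import read_structure

    rows = {}
    for cid, text in pdb_texts.items():
        structure = read_structure(text, peptide_chain)
        rows[cid] = descriptor_vector(structure, params).as_series()
    out = pd.DataFrame(rows).T
    out.index.name = "id"
    return out.reset_index()
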