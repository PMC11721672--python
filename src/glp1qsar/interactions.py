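"""Detection of cross-interface contacts in receptor-peptide complexes.

Five interaction types are detected between the receptor chains and the
peptide chain: hydrogen bonds, hydrophobic (apolar carbon-carbon)
contacts, cation-π, π-π (stacked or T-shaped), and ion-ion pairs. Each
detected contact carries a favorable (non-positive) energy formed from a
fixed per-type scale modulated by smooth distance/angle factors in
[0, 1]. Counts and energy sums roll up into twelve interaction
descriptors; the total count and total energy are exact sums over the
five types.

All detectors are brute-force over cross-interface candidates - complex
sizes in this problem (a receptor, an 11-mer peptide) never warrant
spatial indexing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import EnergyModelParams
from .structure import ComplexStructure

__all__ = [
    "InterfaceInteraction",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_contacts",
    "detect_cation_pi",
    "detect_pi_pi",
    "detect_ion_ion",
    "detect_all",
    "interaction_summaries",
    "INTERACTION_KINDS",
]

INTERACTION_KINDS = ("hbond", "hydrophobic", "cation_pi", "pi_pi", "ion_ion")

_KIND_LABEL = {
    "hbond": "HBond",
    "hydrophobic": "Hydrophobic",
    "cation_pi": "CationPi",
    "pi_pi": "PiPi",
    "ion_ion": "IonIon",
}


@dataclass(frozen=True)
class InterfaceInteraction:
    kind: str
    receptor_atoms: tuple[int, ...]
    peptide_atoms: tuple[int, ...]
    distance: float
    angle: float | None
    energy: float

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not self.receptor_atoms or not self.peptide_atoms:
            raise ValueError("both sides of an interaction must be populated")
        if self.energy > 0:
            raise ValueError("interface interaction energies are capped at 0")


def _ramp(value: float, zero_at: float, one_at: float) -> float:
    """Linear factor clamped to [0, 1]; 1 at ``one_at``, 0 at ``zero_at``."""
    if zero_at == one_at:
        return 1.0
    f = (value - zero_at) / (one_at - zero_at)
    return min(1.0, max(0.0, f))


def _neighbor_map(structure: ComplexStructure) -> dict[int, list[int]]:
    nbrs: dict[int, list[int]] = {i: [] for i in range(len(structure.atoms))}
    for i, j in structure.bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    return nbrs


def _split_sides(structure, rec_idx, pep_idx, i, j):
    """Order a cross-interface atom index pair as (receptor, peptide)."""
    if structure.is_peptide(structure.atoms[i]):
        return (j,), (i,)
    return (i,), (j,)


def detect_hydrogen_bonds(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> list[InterfaceInteraction]:
    """Cross-interface hydrogen bonds.

    With explicit hydrogens: d(H...A) <= 2.5 Å and D-H...A angle >= 120°.
    Without any hydrogens in the structure, a heavy-atom criterion
    applies: d(D...A) <= 3.5 Å. Donors are N/O/S bearing a bonded H (all
    N, plus hydroxyl-type O, in the heavy-atom fallback); acceptors are O,
    S and nitrogens with fewer than three bonded heavy atoms. Atoms of
    formally ionized groups are excluded on both sides - their polar
    contacts are scored through the ion-ion channel.
    """
    params = params or EnergyModelParams.default()
    nbrs = _neighbor_map(structure)
    atoms = structure.atoms
    has_h = any(a.element.upper() == "H" for a in atoms)

    def heavy_neighbors(i):
        return [j for j in nbrs[i] if atoms[j].element.upper() != "H"]

    def h_neighbors(i):
        return [j for j in nbrs[i] if atoms[j].element.upper() == "H"]

    donors: list[tuple[int, list[int]]] = []  # (heavy index, H indices)
    acceptors: list[int] = []
    for i, a in enumerate(atoms):
        elem = a.element.upper()
        if elem not in ("N", "O", "S"):
            continue
        if a.charge_group in ("cation", "anion"):
            continue
        if elem in ("O", "S") or len(heavy_neighbors(i)) < 3:
            acceptors.append(i)
        if has_h:
            hs = h_neighbors(i)
            if hs:
                donors.append((i, hs))
        else:
            if elem == "N" or (elem == "O" and len(heavy_neighbors(i)) < 2):
                donors.append((i, []))

    out: list[InterfaceInteraction] = []
    seen_pairs: set[frozenset[int]] = set()
    for d_idx, hs in donors:
        d_pep = structure.is_peptide(atoms[d_idx])
        for a_idx in acceptors:
            if a_idx == d_idx or structure.is_peptide(atoms[a_idx]) == d_pep:
                continue
            if has_h:
                for h_idx in hs:
                    r_ha = float(np.linalg.norm(atoms[h_idx].xyz - atoms[a_idx].xyz))
                    if r_ha > params.hbond_ha_max:
                        continue
                    v1 = atoms[d_idx].xyz - atoms[h_idx].xyz
                    v2 = atoms[a_idx].xyz - atoms[h_idx].xyz
                    cosang = float(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    )
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if angle < params.hbond_angle_min:
                        continue
                    f_d = _ramp(r_ha, params.hbond_ha_max, params.hbond_ha_ideal)
                    f_a = _ramp(angle, params.hbond_angle_min, 180.0)
                    participants = (d_idx, h_idx)
                    rec, pep = ((a_idx,), participants) if d_pep else (
                        participants, (a_idx,))
                    out.append(InterfaceInteraction(
                        "hbond", rec, pep, r_ha, angle,
                        min(0.0, -params.e_hbond * f_d * f_a)))
            else:
                pair = frozenset((d_idx, a_idx))
                if pair in seen_pairs:
                    continue  # donor/acceptor roles are ambiguous without H
                r_da = float(np.linalg.norm(atoms[d_idx].xyz - atoms[a_idx].xyz))
                if r_da > params.hbond_da_max:
                    continue
                seen_pairs.add(pair)
                f_d = _ramp(r_da, params.hbond_da_max, params.hbond_da_ideal)
                rec, pep = ((a_idx,), (d_idx,)) if d_pep else ((d_idx,), (a_idx,))
                out.append(InterfaceInteraction(
                    "hbond", rec, pep, r_da, None,
                    min(0.0, -params.e_hbond * f_d)))
    return out


def detect_hydrophobic_contacts(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> list[InterfaceInteraction]:
    """Apolar carbon pairs across the interface within 5.0 Å.

    Aromatic ring members and formally charged atoms are excluded: their
    interface contacts are scored through the π and ionic channels.
    """
    params = params or EnergyModelParams.default()
    atoms = structure.atoms
    apolar = [i for i, a in enumerate(atoms)
              if a.polarity_class == "apolar_carbon" and a.charge_group is None]
    rec = [i for i in apolar if not structure.is_peptide(atoms[i])]
    pep = [i for i in apolar if structure.is_peptide(atoms[i])]
    out = []
    for i in rec:
        for j in pep:
            d = float(np.linalg.norm(atoms[i].xyz - atoms[j].xyz))
            if d <= params.hydrophobic_max:
                f = _ramp(d, params.hydrophobic_max, params.hydrophobic_ideal)
                out.append(InterfaceInteraction(
                    "hydrophobic", (i,), (j,), d, None,
                    min(0.0, -params.e_hydrophobic * f)))
    return out


def _folded_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between undirected axes, folded to [0, 90] degrees."""
    c = abs(float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
    return math.degrees(math.acos(min(1.0, c)))


def detect_cation_pi(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> list[InterfaceInteraction]:
    """Cation center within 6.0 Å of a ring centroid, near the ring normal."""
    params = params or EnergyModelParams.default()
    out = []
    for center in structure.charge_centers:
        if center.sign <= 0:
            continue
        c_pep = center.chain_id == structure.peptide_chain
        for ring in structure.rings:
            r_pep = ring.chain_id == structure.peptide_chain
            if c_pep == r_pep:
                continue
            vec = center.center - ring.centroid
            d = float(np.linalg.norm(vec))
            if d < 1e-9 or d > params.cation_pi_max:
                continue
            angle = _folded_angle(ring.normal, vec)
            if angle > params.cation_pi_angle_max:
                continue
            f_d = _ramp(d, params.cation_pi_max, 4.0)
            f_a = _ramp(angle, params.cation_pi_angle_max, 0.0)
            rec, pep = ((ring.atom_indices, center.atom_indices)
                        if c_pep else (center.atom_indices, ring.atom_indices))
            out.append(InterfaceInteraction(
                "cation_pi", tuple(rec), tuple(pep), d, angle,
                min(0.0, -params.e_cation_pi * f_d * f_a)))
    return out


def detect_pi_pi(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> list[InterfaceInteraction]:
    """Stacked (<=5.5 Å, <=30°) or T-shaped (<=7.0 Å, 60-90°) ring pairs."""
    params = params or EnergyModelParams.default()
    out = []
    rec_rings = [r for r in structure.rings
                 if r.chain_id != structure.peptide_chain]
    pep_rings = [r for r in structure.rings
                 if r.chain_id == structure.peptide_chain]
    for r1 in rec_rings:
        for r2 in pep_rings:
            d = float(np.linalg.norm(r1.centroid - r2.centroid))
            angle = _folded_angle(r1.normal, r2.normal)
            stacked = (d <= params.pi_pi_stack_max
                       and angle <= params.pi_pi_stack_angle_max)
            t_shaped = (d <= params.pi_pi_t_max
                        and params.pi_pi_t_angle_min <= angle <= 90.0)
            if not (stacked or t_shaped):
                continue
            f_d = _ramp(d, params.pi_pi_t_max if t_shaped else
                        params.pi_pi_stack_max, 3.8)
            out.append(InterfaceInteraction(
                "pi_pi", tuple(r1.atom_indices), tuple(r2.atom_indices),
                d, angle, min(0.0, -params.e_pi_pi * f_d)))
    return out


def detect_ion_ion(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> list[InterfaceInteraction]:
    """Opposite-sign charge-group centers within 6.0 Å across the interface."""
    params = params or EnergyModelParams.default()
    out = []
    rec = [c for c in structure.charge_centers
           if c.chain_id != structure.peptide_chain]
    pep = [c for c in structure.charge_centers
           if c.chain_id == structure.peptide_chain]
    for c1 in rec:
        for c2 in pep:
            if c1.sign * c2.sign >= 0:
                continue
            d = float(np.linalg.norm(c1.center - c2.center))
            if d > params.ion_ion_max:
                continue
            f_d = _ramp(d, params.ion_ion_max, 3.0)
            out.append(InterfaceInteraction(
                "ion_ion", tuple(c1.atom_indices), tuple(c2.atom_indices),
                d, None, min(0.0, -params.e_ion_ion * f_d)))
    return out


_DETECTORS = {
    "hbond": detect_hydrogen_bonds,
    "hydrophobic": detect_hydrophobic_contacts,
    "cation_pi": detect_cation_pi,
    "pi_pi": detect_pi_pi,
    "ion_ion": detect_ion_ion,
}


def detect_all(
    structure: ComplexStructure, params: EnergyModelParams | None = None
) -> list[InterfaceInteraction]:
    params = params or EnergyModelParams.default()
    out: list[InterfaceInteraction] = []
    for kind in INTERACTION_KINDS:
        out.extend(_DETECTORS[kind](structure, params))
    return out


def interaction_summaries(
    interactions: list[InterfaceInteraction],
) -> dict[str, float]:
    """Roll interactions up into the twelve interaction descriptors.

    ``InteractionCount`` and ``InteractionEnergy`` are the exact sums of
    the five per-type counts and energies.
    """
    counts = {k: 0 for k in INTERACTION_KINDS}
    energies = {k: 0.0 for k in INTERACTION_KINDS}
    for it in interactions:
        counts[it.kind] += 1
        energies[it.kind] += it.energy
    out: dict[str, float] = {}
    for kind in INTERACTION_KINDS:
        out[f"{_KIND_LABEL[kind]}Count"] = float(counts[kind])
    for kind in INTERACTION_KINDS:
        out[f"{_KIND_LABEL[kind]}Energy"] = energies[kind]
    out["InteractionCount"] = float(sum(counts.values()))
    out["InteractionEnergy"] = sum(energies.values())
    return out
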