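"""Interface-contact detectors versus planted geometries and a naive oracle."""

import math

import numpy as np
import pytest

from glp1qsar import (
    detect_all,
    detect_cation_pi,
    detect_hydrogen_bonds,
    detect_hydrophobic_contacts,
    detect_ion_ion,
    detect_pi_pi,
    interaction_summaries,
    read_structure,
    write_pdb,
)
from glp1qsar.interactions import InterfaceInteraction
from glp1qsar.structure import AtomRecord


def _structure(atoms):
    return read_structure(write_pdb(atoms), "P")


def _ring(center, normal, chain, resnum, serial0):
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1, 0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return [
        AtomRecord(serial0 + k, f"C{k+1}", "C", "BNZ", resnum, chain,
                   np.asarray(center) + 1.39 * (math.cos(k*math.pi/3) * u
                                                + math.sin(k*math.pi/3) * v))
        for k in range(6)
    ]


def hbond_case(d, angle):
    th = math.radians(angle)
    h = np.array([d, 0.0, 0.0])
    n = h + 1.01 * np.array([-math.cos(th), math.sin(th), 0.0])
    return _structure([
        AtomRecord(1, "C", "C", "CBX", 1, "A", np.array([-1.23, 0.0, 0.0])),
        AtomRecord(2, "O", "O", "CBX", 1, "A", np.zeros(3)),
        AtomRecord(3, "N", "N", "AMN", 1, "P", n),
        AtomRecord(4, "H", "H", "AMN", 1, "P", h),
    ])


class TestHydrogenBonds:
    def test_ideal_geometry_detected_with_negative_energy(self):
        found = detect_hydrogen_bonds(hbond_case(2.0, 180.0))
        assert len(found) == 1
        assert found[0].energy < 0
        assert found[0].distance == pytest.approx(2.0)

    @pytest.mark.parametrize("d, angle", [(3.5, 180.0), (2.0, 90.0)])
    def test_out_of_criterion_geometry_rejected(self, d, angle):
        assert detect_hydrogen_bonds(hbond_case(d, angle)) == []

    def test_heavy_atom_fallback_without_hydrogens(self):
        s = _structure([
            AtomRecord(1, "C", "C", "CBX", 1, "A", np.array([-1.23, 0.0, 0.0])),
            AtomRecord(2, "O", "O", "CBX", 1, "A", np.zeros(3)),
            AtomRecord(3, "N", "N", "AMN", 1, "P", np.array([3.0, 0.0, 0.0])),
        ])
        found = detect_hydrogen_bonds(s)
        assert len(found) == 1 and found[0].angle is None


def hydrophobic_case(d, partner="ALK"):
    atoms = [AtomRecord(1, "C1", "C", "ALK", 1, "A", np.zeros(3))]
    if partner == "ALK":
        atoms.append(AtomRecord(2, "C1", "C", "ALK", 1, "P",
                                np.array([d, 0.0, 0.0])))
    else:  # carbonyl group, oxygen at distance d
        atoms.append(AtomRecord(2, "O", "O", "CBX", 1, "P",
                                np.array([d, 0.0, 0.0])))
        atoms.append(AtomRecord(3, "C", "C", "CBX", 1, "P",
                                np.array([d + 1.23, 0.0, 0.0])))
    return _structure(atoms)


class TestHydrophobicContacts:
    def test_apolar_pair_within_cutoff(self):
        assert len(detect_hydrophobic_contacts(hydrophobic_case(4.0))) == 1

    def test_beyond_cutoff(self):
        assert detect_hydrophobic_contacts(hydrophobic_case(6.0)) == []

    def test_polar_partner_not_counted(self):
        assert detect_hydrophobic_contacts(
            hydrophobic_case(4.0, partner="CBX")) == []


def cation_pi_case(d, angle):
    th = math.radians(angle)
    cation = d * np.array([math.sin(th), 0.0, math.cos(th)])
    return _structure(
        _ring(np.zeros(3), [0, 0, 1], "A", 1, 1)
        + [AtomRecord(7, "N", "N", "NH4", 1, "P", cation)]
    )


class TestCationPi:
    def test_on_axis_detected(self):
        assert len(detect_cation_pi(cation_pi_case(4.5, 0.0))) == 1

    @pytest.mark.parametrize("d, angle", [(10.0, 0.0), (4.5, 90.0)])
    def test_off_criterion_rejected(self, d, angle):
        assert detect_cation_pi(cation_pi_case(d, angle)) == []


def pi_pi_case(d, angle):
    th = math.radians(angle)
    n2 = np.array([math.sin(th), 0.0, math.cos(th)])
    return _structure(
        _ring(np.zeros(3), [0, 0, 1], "A", 1, 1)
        + _ring(np.array([0.0, 0.0, d]), n2, "P", 1, 7)
    )


class TestPiPi:
    def test_parallel_stack(self):
        found = detect_pi_pi(pi_pi_case(3.8, 0.0))
        assert len(found) == 1

    def test_t_shaped(self):
        assert len(detect_pi_pi(pi_pi_case(5.0, 90.0))) == 1

    def test_distant_parallel_rejected(self):
        assert detect_pi_pi(pi_pi_case(9.0, 0.0)) == []


def ion_case(d, like_signs=False):
    c = np.zeros(3)
    o1 = np.array([1.13, 0.71, 0.0])
    o2 = np.array([1.13, -0.71, 0.0])
    atoms = [
        AtomRecord(1, "C", "C", "ACT", 1, "A", c),
        AtomRecord(2, "O1", "O", "ACT", 1, "A", o1),
        AtomRecord(3, "O2", "O", "ACT", 1, "A", o2),
    ]
    center = (c + o1 + o2) / 3
    if like_signs:
        base = center + np.array([d, 0.0, 0.0]) - np.array([0.75, 0.0, 0.0])
        atoms += [
            AtomRecord(4, "C", "C", "ACT", 1, "P", base),
            AtomRecord(5, "O1", "O", "ACT", 1, "P", base + [1.13, 0.71, 0]),
            AtomRecord(6, "O2", "O", "ACT", 1, "P", base + [1.13, -0.71, 0]),
        ]
    else:
        atoms.append(AtomRecord(4, "N", "N", "NH4", 1, "P",
                                center + np.array([d, 0.0, 0.0])))
    return _structure(atoms)


class TestIonIon:
    def test_salt_bridge_detected(self):
        assert len(detect_ion_ion(ion_case(3.0))) == 1

    def test_beyond_cutoff(self):
        assert detect_ion_ion(ion_case(9.0)) == []

    def test_like_signs_never_counted(self):
        assert detect_ion_ion(ion_case(3.0, like_signs=True)) == []


class TestSummaries:
    def test_counts_sum_identity(self):
        kinds = (["hbond"] * 2 + ["hydrophobic"] + ["pi_pi"] + ["ion_ion"] * 3)
        fake = [
            InterfaceInteraction(k, (1,), (2,), 3.0, None, -1.0) for k in kinds
        ]
        summ = interaction_summaries(fake)
        assert summ["InteractionCount"] == 7
        assert summ["InteractionEnergy"] == pytest.approx(-7.0)

    def test_empty_list_all_zero(self):
        summ = interaction_summaries([])
        assert all(v == 0 for v in summ.values())

    def test_one_of_each_kind_on_toy_complex(self, full_toy_structure):
        summ = interaction_summaries(detect_all(full_toy_structure))
        for key in ("HBondCount", "HydrophobicCount", "CationPiCount",
                    "PiPiCount", "IonIonCount"):
            assert summ[key] == 1
        assert summ["InteractionCount"] == 5


def test_participants_respect_the_interface(full_toy_structure):
    s = full_toy_structure
    for it in detect_all(s):
        assert all(not s.is_peptide(s.atoms[i]) for i in it.receptor_atoms)
        assert all(s.is_peptide(s.atoms[i]) for i in it.peptide_atoms)
        assert it.energy <= 0


def test_detectors_agree_with_naive_all_pairs_oracle(full_toy_structure):
    """Re-derive every count with plain nested loops over the annotations."""
    s = full_toy_structure
    atoms = s.atoms
    nbrs = {i: set() for i in range(len(atoms))}
    for i, j in s.bonds:
        nbrs[i].add(j)
        nbrs[j].add(i)

    def side(i):
        return s.is_peptide(atoms[i])

    # hydrogen bonds
    hb = 0
    for d_idx, a in enumerate(atoms):
        if a.element not in ("N", "O", "S") or a.charge_group in ("cation", "anion"):
            continue
        hs = [j for j in nbrs[d_idx] if atoms[j].element == "H"]
        for h in hs:
            for acc, b in enumerate(atoms):
                if (b.element not in ("N", "O", "S") or side(acc) == side(d_idx)
                        or b.charge_group in ("cation", "anion")):
                    continue
                heavy = [j for j in nbrs[acc] if atoms[j].element != "H"]
                if b.element == "N" and len(heavy) >= 3:
                    continue
                r = np.linalg.norm(atoms[h].xyz - b.xyz)
                if r > 2.5:
                    continue
                v1, v2 = a.xyz - atoms[h].xyz, b.xyz - atoms[h].xyz
                ang = math.degrees(math.acos(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
                if ang >= 120.0:
                    hb += 1
    # hydrophobic
    phob = 0
    ap = [i for i, a in enumerate(atoms)
          if a.polarity_class == "apolar_carbon" and a.charge_group is None]
    for i in ap:
        for j in ap:
            if side(i) or not side(j):
                continue
            if np.linalg.norm(atoms[i].xyz - atoms[j].xyz) <= 5.0:
                phob += 1
    # cation-pi, pi-pi, ion-ion from the annotated groups
    cpi = 0
    for c in s.charge_centers:
        if c.sign <= 0:
            continue
        for r in s.rings:
            if (c.chain_id == s.peptide_chain) == (r.chain_id == s.peptide_chain):
                continue
            vec = c.center - r.centroid
            d = np.linalg.norm(vec)
            cosang = abs(np.dot(r.normal, vec) / d)
            if d <= 6.0 and math.degrees(math.acos(min(1, cosang))) <= 45.0:
                cpi += 1
    pp = 0
    for r1 in s.rings:
        for r2 in s.rings:
            if r1.chain_id == s.peptide_chain or r2.chain_id != s.peptide_chain:
                continue
            d = np.linalg.norm(r1.centroid - r2.centroid)
            ang = math.degrees(math.acos(min(1, abs(np.dot(r1.normal, r2.normal)))))
            if (d <= 5.5 and ang <= 30.0) or (d <= 7.0 and 60.0 <= ang <= 90.0):
                pp += 1
    ii = 0
    for c1 in s.charge_centers:
        for c2 in s.charge_centers:
            if c1.chain_id == s.peptide_chain or c2.chain_id != s.peptide_chain:
                continue
            if c1.sign * c2.sign < 0 and np.linalg.norm(c1.center - c2.center) <= 6.0:
                ii += 1

    summ = interaction_summaries(detect_all(s))
    assert summ["HBondCount"] == hb
    assert summ["HydrophobicCount"] == phob
    assert summ["CationPiCount"] == cpi
    assert summ["PiPiCount"] == pp
    assert summ["IonIonCount"] == ii
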