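"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all fully deterministic under a fixed seed:

* :func:`gen_descriptor_table` - descriptor matrices with a sparse linear
  pEC50 signal, homoscedastic Gaussian noise and controllable pairwise
  collinearity. The defaults mirror the study conditions of the real
  regression problem: n = 31 peptides, 26 canonically named descriptors,
  two true terms, and a noise level giving a population R² of 0.6 -
  the regime in which the real model selection operates.
* :func:`gen_toy_complex` - two-chain PDB structures in which each
  requested interface interaction is realized by a minimal atom group at
  an explicit geometry (with >= 10% margin on every detector threshold),
  plus far-away decoy atoms that violate all criteria.
* :func:`gen_scan_dataset` - Ala/Aib scan peptide sets with additive
  per-position potency effects plus a constant Cα-methylation effect,
  wired into scan pairs exactly like the real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import DESCRIPTOR_NAMES
from .sar import PeptideRecord, ScanPair
from .structure import AtomRecord, write_pdb

__all__ = [
    "DescriptorSimSpec",
    "ToyComplexSpec",
    "ScanSimSpec",
    "gen_descriptor_table",
    "gen_toy_complex",
    "gen_scan_dataset",
]


# ---------------------------------------------------------------------------
# Descriptor tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorSimSpec:
    """Simulation spec for a descriptor table with a planted linear signal.

    ``noise_sd`` defaults to sqrt(2/3) so that with the default two
    unit-variance true terms of weights (0.8, 0.6) the population R² is
    (0.8² + 0.6²) / (0.8² + 0.6² + 2/3) = 0.6.
    """

    n: int = 31
    descriptor_names: tuple[str, ...] = DESCRIPTOR_NAMES
    true_terms: tuple[str, ...] = ("BEpot", "BSvdw")
    true_weights: tuple[float, ...] = (0.8, 0.6)
    intercept: float = 7.9
    noise_sd: float = math.sqrt(2.0 / 3.0)
    collinearity: dict = field(default_factory=dict)  # (name_a, name_b) -> rho
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.true_terms) != len(self.true_weights):
            raise ValueError("one weight per true term")
        unknown = set(self.true_terms) - set(self.descriptor_names)
        if unknown:
            raise ValueError(f"true terms not among descriptors: {unknown}")
        for (a, b), rho in self.collinearity.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"correlation for ({a}, {b}) must be in (-1, 1)")


def gen_descriptor_table(spec: DescriptorSimSpec | None = None) -> pd.DataFrame:
    """Descriptor table with columns id, pec50 and the named descriptors."""
    spec = spec or DescriptorSimSpec()
    p = len(spec.descriptor_names)
    idx = {name: i for i, name in enumerate(spec.descriptor_names)}
    corr = np.eye(p)
    for (a, b), rho in spec.collinearity.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "requested correlation structure is not positive definite"
        ) from None
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n, p))
    x = z @ chol.T
    y = np.full(spec.n, spec.intercept, dtype=float)
    for term, w in zip(spec.true_terms, spec.true_weights):
        y += w * x[:, idx[term]]
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, size=spec.n)
    table = pd.DataFrame(x, columns=list(spec.descriptor_names))
    table.insert(0, "pec50", y)
    table.insert(0, "id", [f"SYN-{i:03d}" for i in range(spec.n)])
    return table


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Planted interface interactions plus decoy atoms for a toy complex.

    Each planted entry is ``(kind, geometry)`` with kind one of
    hbond / hydrophobic / cation_pi / pi_pi / ion_ion and geometry keys
    ``distance`` (Å) and, where meaningful, ``angle`` (degrees).
    """

    planted: tuple = ()
    decoy_atoms: int = 0
    decoy_radius: float = 30.0
    receptor_chain: str = "A"
    peptide_chain: str = "P"

    _SITE_SPACING = 25.0

    def __post_init__(self) -> None:
        for kind, _ in self.planted:
            if kind not in ("hbond", "hydrophobic", "cation_pi", "pi_pi",
                            "ion_ion"):
                raise ValueError(f"unknown interaction kind {kind!r}")


def _ring_atoms(center: np.ndarray, normal: np.ndarray, resname: str,
                resnum: int, chain: str, start_serial: int,
                radius: float = 1.39) -> list[AtomRecord]:
    normal = normal / np.linalg.norm(normal)
    # build two in-plane unit vectors
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(normal @ ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    atoms = []
    for k in range(6):
        theta = k * math.pi / 3.0
        xyz = center + radius * (math.cos(theta) * u + math.sin(theta) * v)
        atoms.append(AtomRecord(start_serial + k, f"C{k + 1}", "C", resname,
                                resnum, chain, xyz))
    return atoms


_MARGIN = 0.10


def _require_margin(kind: str, value: float, limit: float, upper: bool) -> None:
    ok = value <= limit * (1 - _MARGIN) if upper else value >= limit * (1 + _MARGIN)
    if not ok:
        raise ValueError(
            f"{kind}: geometry value {value} violates the 10% margin against "
            f"the detector limit {limit}"
        )


def gen_toy_complex(spec: ToyComplexSpec) -> str:
    """Emit a two-chain PDB text realizing the planted interactions."""
    atoms: list[AtomRecord] = []
    serial = [1]
    resnum = {"A": 0, "P": 0}

    def add(name, element, resname, chain, xyz, new_residue=False):
        if new_residue or resnum[chain] == 0:
            resnum[chain] += 1
        atoms.append(AtomRecord(serial[0], name, element, resname,
                                resnum[chain], chain, np.asarray(xyz, float)))
        serial[0] += 1

    rc, pc = spec.receptor_chain, spec.peptide_chain
    for site, (kind, geom) in enumerate(spec.planted):
        o = np.array([spec._SITE_SPACING * site, 0.7 * site, 0.0])
        if kind == "hbond":
            d = float(geom.get("distance", 2.0))
            angle = float(geom.get("angle", 180.0))
            _require_margin(kind, d, 2.5, upper=True)
            if angle < 120.0 * (1 + _MARGIN):
                raise ValueError("hbond angle too shallow for the 10% margin")
            add("C", "C", "CBX", rc, o + [-1.23, 0, 0], new_residue=True)
            add("O", "O", "CBX", rc, o)
            h = o + [d, 0.0, 0.0]
            th = math.radians(angle)
            n = h + 1.01 * np.array([-math.cos(th), math.sin(th), 0.0])
            add("N", "N", "AMN", pc, n, new_residue=True)
            add("H", "H", "AMN", pc, h)
        elif kind == "hydrophobic":
            d = float(geom.get("distance", 4.0))
            _require_margin(kind, d, 5.0, upper=True)
            add("C1", "C", "ALK", rc, o, new_residue=True)
            add("C1", "C", "ALK", pc, o + [d, 0, 0], new_residue=True)
        elif kind == "cation_pi":
            d = float(geom.get("distance", 4.5))
            angle = float(geom.get("angle", 0.0))
            _require_margin(kind, d, 6.0, upper=True)
            if angle > 45.0 * (1 - _MARGIN):
                raise ValueError("cation-pi angle too oblique for the margin")
            rn = resnum[rc] + 1
            resnum[rc] = rn
            ring = _ring_atoms(o, np.array([0.0, 0.0, 1.0]), "BNZ", rn, rc,
                               serial[0])
            atoms.extend(ring)
            serial[0] += 6
            th = math.radians(angle)
            cation = o + d * np.array([math.sin(th), 0.0, math.cos(th)])
            add("N", "N", "NH4", pc, cation, new_residue=True)
        elif kind == "pi_pi":
            d = float(geom.get("distance", 3.8))
            angle = float(geom.get("angle", 0.0))
            stacked = angle <= 45.0
            if stacked:
                _require_margin(kind, d, 5.5, upper=True)
                if angle > 30.0 * (1 - _MARGIN) and angle != 0.0:
                    raise ValueError("stacked pi-pi angle violates the margin")
            else:
                _require_margin(kind, d, 7.0, upper=True)
                if angle < 60.0 * (1 + _MARGIN) and angle != 90.0:
                    raise ValueError("T-shaped pi-pi angle violates the margin")
            rn = resnum[rc] + 1
            resnum[rc] = rn
            atoms.extend(_ring_atoms(o, np.array([0.0, 0.0, 1.0]), "BNZ",
                                     rn, rc, serial[0]))
            serial[0] += 6
            th = math.radians(angle)
            normal2 = np.array([math.sin(th), 0.0, math.cos(th)])
            rn = resnum[pc] + 1
            resnum[pc] = rn
            atoms.extend(_ring_atoms(o + [0, 0, d], normal2, "BNZ", rn, pc,
                                     serial[0]))
            serial[0] += 6
        elif kind == "ion_ion":
            d = float(geom.get("distance", 3.0))
            _require_margin(kind, d, 6.0, upper=True)
            c = o
            o1 = o + [1.13, 0.71, 0.0]
            o2 = o + [1.13, -0.71, 0.0]
            add("C", "C", "ACT", rc, c, new_residue=True)
            add("O1", "O", "ACT", rc, o1)
            add("O2", "O", "ACT", rc, o2)
            center = (c + o1 + o2) / 3.0
            add("N", "N", "NH4", pc, center + [d, 0, 0], new_residue=True)

    n_sites = max(len(spec.planted), 1)
    hub = np.array([spec._SITE_SPACING * (n_sites - 1) / 2.0, 0.0, 45.0])
    for k in range(spec.decoy_atoms):
        theta = 2.0 * math.pi * k / max(spec.decoy_atoms, 1) + 0.31
        xyz = hub + np.array([
            spec.decoy_radius * math.cos(theta),
            spec.decoy_radius * math.sin(theta),
            1.7 * k % 11.0,
        ])
        chain = rc if k % 2 == 0 else pc
        add("C1", "C", "ALK", chain, xyz, new_residue=True)

    if not atoms:
        raise ValueError("empty spec: nothing to emit")
    # chains must both be populated for a parseable complex
    chains = {a.chain_id for a in atoms}
    for needed in (rc, pc):
        if needed not in chains:
            anchor = hub + np.array([0.0, 0.0, 20.0 if needed == rc else 28.0])
            add("C1", "C", "ALK", needed, anchor, new_residue=True)

    coords = np.array([a.xyz for a in atoms])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    # overlap guard between atoms of different residues
    keys = [(a.chain_id, a.residue_number) for a in atoms]
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if keys[i] != keys[j] and d[i, j] < 1.9:
                raise ValueError(
                    f"overlapping placements: atoms {atoms[i].serial} and "
                    f"{atoms[j].serial} are {d[i, j]:.2f} Å apart"
                )
    return write_pdb(atoms)


# ---------------------------------------------------------------------------
# Scan datasets
# ---------------------------------------------------------------------------

_PARENT_SEQ = ("His", "Aib", "Glu", "Gly", "Thr", "Phe(2-F)", "Thr", "Ser",
               "Asp", "Bip", "Bip")
_MPARENT_SEQ = ("His", "Aib", "Glu", "Gly", "Thr", "aMe-Phe(2-F)", "Thr",
                "Ser", "Asp", "Bip", "Bip")


@dataclass(frozen=True)
class ScanSimSpec:
    """Spec for a synthetic Ala/Aib scan dataset.

    Response model (before noise): Ala analog at position i has
    ``parent_pec50 + ala_effects[i]``; the Aib analog has
    ``parent_pec50 + aib_effects[i] + methylation_constant``; the two
    parents differ by exactly the methylation constant.
    """

    positions: tuple[int, ...] = tuple(range(1, 12))
    ala_effects: dict = field(default_factory=dict)
    aib_effects: dict = field(default_factory=dict)
    methylation_constant: float = 0.97
    parent_pec50: float = 9.92
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        bad = [p for p in self.positions if not 1 <= p <= 11]
        if bad:
            raise ValueError(f"positions out of range: {bad}")


def gen_scan_dataset(
    spec: ScanSimSpec | None = None,
) -> tuple[list[PeptideRecord], list[ScanPair]]:
    """Parent, Ala-scan and Aib-scan records plus their pair wiring."""
    spec = spec or ScanSimSpec()
    rng = np.random.default_rng(spec.seed)

    def noise() -> float:
        return float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0

    records: list[PeptideRecord] = []
    pairs: list[ScanPair] = []

    ala_parent = PeptideRecord(
        id="SYN-ALA-P", sequence=_PARENT_SEQ, series="parent",
        pec50=spec.parent_pec50 + noise(),
    )
    aib_parent = PeptideRecord(
        id="SYN-AIB-P", sequence=_MPARENT_SEQ, series="parent",
        pec50=spec.parent_pec50 + spec.methylation_constant + noise(),
    )
    records += [ala_parent, aib_parent]
    pairs.append(ScanPair(position=6, aib_id="SYN-AIB-P", ala_id="SYN-ALA-P",
                          role="parent"))

    for pos in spec.positions:
        ala_seq = list(_PARENT_SEQ)
        ala_seq[pos - 1] = "Ala"
        aib_seq = list(_MPARENT_SEQ)
        aib_seq[pos - 1] = "Aib"
        ala_id, aib_id = f"SYN-ALA-{pos:02d}", f"SYN-AIB-{pos:02d}"
        records.append(PeptideRecord(
            id=ala_id, sequence=tuple(ala_seq), series="ala_scan",
            pec50=spec.parent_pec50 + spec.ala_effects.get(pos, 0.0) + noise(),
        ))
        records.append(PeptideRecord(
            id=aib_id, sequence=tuple(aib_seq), series="aib_scan",
            pec50=(spec.parent_pec50 + spec.aib_effects.get(pos, 0.0)
                   + spec.methylation_constant + noise()),
        ))
        pairs.append(ScanPair(position=pos, aib_id=aib_id, ala_id=ala_id))
    return records, pairs
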