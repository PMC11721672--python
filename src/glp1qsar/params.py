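"""Energy-model and geometry parameters for the interface descriptors.

All energies are in kJ/mol, distances in Å, angles in degrees. The
defaults implement a documented surrogate energy model: a generic
Lennard-Jones/Coulomb nonbonded table with a 10->12 Å smooth switch, a
generalized-Born polar solvation term (solute dielectric 1, solvent 78),
SASA-proportional nonpolar solvation, and fixed per-interaction energy
scales for the five interface contact types. Solute radii follow the
molecular-surface parameterization used for the solvation model
(polar hydrogens 0.32, other hydrogens 1.017, C 1.8, O 1.344, N 1.14,
S 2.0; probe 1.4).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


def _default_solute_radii() -> dict[str, float]:
    return {
        "polar_hydrogen": 0.32,
        "apolar_hydrogen": 1.017,
        "C": 1.8,
        "O": 1.344,
        "N": 1.14,
        "S": 2.0,
        # halogens occur in the ring-substituted phenylalanines
        "F": 1.30,
        "CL": 1.75,
        "BR": 1.85,
    }


def _default_lj_sigma() -> dict[str, float]:
    return {"H": 2.50, "C": 3.40, "N": 3.25, "O": 3.00, "S": 3.60,
            "F": 3.10, "CL": 3.47, "BR": 3.60}


def _default_lj_epsilon() -> dict[str, float]:
    return {"H": 0.066, "C": 0.458, "N": 0.711, "O": 0.879, "S": 1.046,
            "F": 0.255, "CL": 1.108, "BR": 1.300}


@dataclass
class EnergyModelParams:
    """Tunable constants of the surrogate interface energy model."""

    probe_radius: float = 1.4
    solute_radii: dict[str, float] = field(default_factory=_default_solute_radii)
    dielectric_solvent: float = 78.0
    dielectric_solute: float = 1.0
    coulomb_constant: float = 1389.35  # kJ Å / mol per unit-charge pair
    lj_sigma: dict[str, float] = field(default_factory=_default_lj_sigma)
    lj_epsilon: dict[str, float] = field(default_factory=_default_lj_epsilon)
    cutoff: float = 12.0
    switch_on: float = 10.0

    # solvation surface coefficients, kJ/mol/Å^2
    surface_tension: float = 0.03          # hydrophobic term, apolar SASA
    sasa_vdw_coeff: float = -0.06          # solute-solvent vdw term, total SASA

    # partial-charge template (unit formal charges added on ionized groups)
    q_polar_hydrogen: float = 0.40
    q_nitrogen: float = -0.40
    q_oxygen: float = -0.50
    q_sulfur: float = -0.15
    q_polar_carbon: float = 0.45

    # per-interaction energy scales (favorable magnitudes)
    e_hbond: float = 12.0
    e_hydrophobic: float = 2.0
    e_cation_pi: float = 8.0
    e_pi_pi: float = 6.0
    e_ion_ion: float = 10.0

    # interaction geometry thresholds
    hbond_ha_max: float = 2.5
    hbond_ha_ideal: float = 1.8
    hbond_angle_min: float = 120.0
    hbond_da_max: float = 3.5       # heavy-atom fallback
    hbond_da_ideal: float = 2.8
    hydrophobic_max: float = 5.0
    hydrophobic_ideal: float = 4.0
    cation_pi_max: float = 6.0
    cation_pi_angle_max: float = 45.0
    pi_pi_stack_max: float = 5.5
    pi_pi_stack_angle_max: float = 30.0
    pi_pi_t_max: float = 7.0
    pi_pi_t_angle_min: float = 60.0
    ion_ion_max: float = 6.0

    sasa_points: int = 256

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.solute_radii.values()):
            raise ValueError("solute radii must be positive")
        if self.dielectric_solvent < 1 or self.dielectric_solute < 1:
            raise ValueError("dielectric constants must be >= 1")
        if not self.switch_on < self.cutoff:
            raise ValueError("switch_on must be below the cutoff")

    @classmethod
    def default(cls) -> "EnergyModelParams":
        return cls()

    @classmethod
    def from_json(cls, path: str) -> "EnergyModelParams":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    def solute_radius(self, element: str, polarity_class: str | None) -> float:
        elem = element.upper()
        if elem == "H":
            key = ("polar_hydrogen" if polarity_class == "polar_hydrogen"
                   else "apolar_hydrogen")
            return self.solute_radii[key]
        return self.solute_radii[elem]
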