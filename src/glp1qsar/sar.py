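"""Potency SAR analysis for ultra-short GLP-1 receptor agonist peptides.

This module carries the curated potency dataset of the 11-mer agonist
series (cAMP EC50 / pEC50 for the Phe6-modification, Ala-scan and Aib-scan
analogs) and implements the Ala/Aib Cα-methylation decomposition: the
per-position change in pEC50 attributable to replacing the Cα-hydrogen by
a methyl group, referenced against the position-6 parent pair

    dpEC50(i) = pEC50(Aib, i) - pEC50(Ala, i) - c

where ``c`` is the pEC50 gain of Cα-methylating position 6 of the parent
peptide (0.97 log units for this dataset).

Potencies follow the molar convention pEC50 = -log10(EC50 [M]), i.e.
``pEC50 = 9 - log10(EC50 [nM])``, so 0.1 nM maps to 10.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RESIDUE_TOKENS",
    "POTENCY_CLASSES",
    "PeptideRecord",
    "ScanPair",
    "MethylationContribution",
    "ec50_to_pec50",
    "pec50_to_ec50",
    "reference_methylation_constant",
    "methylation_contribution",
    "build_methylation_table",
    "methylation_frame",
    "potency_class",
    "scan_series_r2",
    "load_peptide_records",
    "load_peptide_table",
    "load_scan_pairs",
    "load_potency_profile",
]

#: Closed vocabulary of residue tokens occurring in the 11-mer series.
RESIDUE_TOKENS = frozenset(
    {
        "His", "Aib", "Glu", "Gly", "Thr", "Ser", "Asp", "Ala", "Bip",
        "Hph", "Tyr", "Trp", "D-Phe", "Phe",
        "Phe(2-F)", "Phe(2-Br)", "Phe(2-Cl)", "Phe(2-CF3)", "Phe(2-CH3)",
        "Phe(2-NO2)", "Phe(2-CN)", "Phe(3-CF3)", "Phe(2,6-F)",
        "Phe(3,4,5-F)", "Phe(2,3,4,5,6-F)",
        "aMe-Phe", "aMe-Phe(2-F)",
    }
)

SERIES_TAGS = frozenset({"phe6_mod", "ala_scan", "aib_scan", "parent"})

#: Ordinal potency classes, most potent first (decade-fold bins vs parent).
POTENCY_CLASSES = ("parent_like", "reduced", "weak", "very_weak", "censored")


def ec50_to_pec50(ec50_nm: float) -> float:
    """Convert an EC50 in nM to pEC50 (molar convention).

    Raises ``ValueError`` for non-positive or non-finite input.
    """
    if not math.isfinite(ec50_nm) or ec50_nm <= 0:
        raise ValueError(f"EC50 must be positive and finite, got {ec50_nm!r}")
    return 9.0 - math.log10(ec50_nm)


def pec50_to_ec50(pec50: float) -> float:
    """Inverse of :func:`ec50_to_pec50`; returns EC50 in nM."""
    if not math.isfinite(pec50):
        raise ValueError(f"pEC50 must be finite, got {pec50!r}")
    return 10.0 ** (9.0 - pec50)


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide of the series with its sequence and assay read-outs.

    ``pec50`` holds the printed pEC50 where one is tabulated (the analysis
    input actually used downstream); censored records (EC50 out of assay
    range, ``> 1000 nM``) carry ``ec50_nm=None`` but may still carry a
    printed pEC50.
    """

    id: str
    sequence: tuple[str, ...]
    ec50_nm: float | None = None
    censored: bool = False
    emax_pct: float | None = None
    pec50: float | None = None
    series: str = "parent"
    in_training_31: bool = False
    c_terminal_amide: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != 11:
            raise ValueError(
                f"{self.id}: sequence must have exactly 11 residues, "
                f"got {len(self.sequence)}"
            )
        unknown = [t for t in self.sequence if t not in RESIDUE_TOKENS]
        if unknown:
            raise ValueError(f"{self.id}: unknown residue tokens {unknown}")
        if self.series not in SERIES_TAGS:
            raise ValueError(f"{self.id}: unknown series tag {self.series!r}")
        if self.censored and self.ec50_nm is not None:
            raise ValueError(f"{self.id}: censored record carries a finite EC50")
        if not self.censored and self.ec50_nm is not None and self.ec50_nm <= 0:
            raise ValueError(f"{self.id}: EC50 must be positive")

    @property
    def pec50_from_ec50(self) -> float | None:
        if self.censored or self.ec50_nm is None:
            return None
        return ec50_to_pec50(self.ec50_nm)


@dataclass(frozen=True)
class ScanPair:
    """An Aib/Ala analog pair sharing a scanned position."""

    position: int
    aib_id: str
    ala_id: str
    role: str = "scan"  # "parent" for the position-6 reference pair

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 11:
            raise ValueError(f"position must be in 1..11, got {self.position}")
        if self.role not in ("scan", "parent"):
            raise ValueError(f"unknown pair role {self.role!r}")


@dataclass(frozen=True)
class MethylationContribution:
    """Cα-methylation contribution at one position (one Aib/Ala pair)."""

    position: int
    aib_id: str
    ala_id: str
    pec50_aib: float
    pec50_ala: float
    reference_constant: float
    dpec50: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        expected = self.pec50_aib - self.pec50_ala - self.reference_constant
        if math.isnan(self.dpec50):
            object.__setattr__(self, "dpec50", expected)
        elif abs(self.dpec50 - expected) > 1e-12:
            raise ValueError(
                f"position {self.position}: dpec50 {self.dpec50} inconsistent "
                f"with its inputs (expected {expected})"
            )


def reference_methylation_constant(
    pec50_aib_parent: float, pec50_ala_parent: float
) -> float:
    """Position-6 Cα-methylation reference: pEC50(α-Me parent) − pEC50(parent)."""
    if not (math.isfinite(pec50_aib_parent) and math.isfinite(pec50_ala_parent)):
        raise ValueError("parent pEC50 values must be finite")
    return pec50_aib_parent - pec50_ala_parent


def methylation_contribution(
    pec50_aib: float, pec50_ala: float, constant: float
) -> float:
    """Per-position Cα-methylation contribution, corrected by ``constant``."""
    for name, v in (("pec50_aib", pec50_aib), ("pec50_ala", pec50_ala),
                    ("constant", constant)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    return pec50_aib - pec50_ala - constant


def build_methylation_table(
    records: Iterable[PeptideRecord] | Mapping[str, PeptideRecord],
    pairs: Sequence[ScanPair],
    constant: float | None = None,
) -> list[MethylationContribution]:
    """Assemble the per-position methylation decomposition for a scan dataset.

    The reference constant is computed first from the pair flagged
    ``role="parent"`` (unless overridden), then applied uniformly to every
    ``role="scan"`` pair. Rows are returned in ascending position order.
    """
    if isinstance(records, Mapping):
        by_id = dict(records)
    else:
        by_id = {r.id: r for r in records}

    def _pec50(pid: str) -> float:
        try:
            rec = by_id[pid]
        except KeyError:
            raise ValueError(f"unknown peptide id {pid!r}") from None
        if rec.pec50 is None:
            raise ValueError(f"record {pid!r} has no pEC50")
        return rec.pec50

    if constant is None:
        parents = [p for p in pairs if p.role == "parent"]
        if len(parents) != 1:
            raise ValueError(
                f"need exactly one parent pair to define the reference "
                f"constant, got {len(parents)}"
            )
        parent = parents[0]
        constant = reference_methylation_constant(
            _pec50(parent.aib_id), _pec50(parent.ala_id)
        )

    rows = []
    for pair in sorted((p for p in pairs if p.role == "scan"),
                       key=lambda p: p.position):
        a, b = _pec50(pair.aib_id), _pec50(pair.ala_id)
        rows.append(
            MethylationContribution(
                position=pair.position,
                aib_id=pair.aib_id,
                ala_id=pair.ala_id,
                pec50_aib=a,
                pec50_ala=b,
                reference_constant=constant,
            )
        )
    return rows


def methylation_frame(rows: Sequence[MethylationContribution]) -> pd.DataFrame:
    """Tabular view of a methylation decomposition (unrounded values)."""
    return pd.DataFrame(
        {
            "position": [r.position for r in rows],
            "aib_id": [r.aib_id for r in rows],
            "ala_id": [r.ala_id for r in rows],
            "pec50_aib": [r.pec50_aib for r in rows],
            "pec50_ala": [r.pec50_ala for r in rows],
            "reference_constant": [r.reference_constant for r in rows],
            "dpec50": [r.dpec50 for r in rows],
        }
    )


def potency_class(
    ec50_nm: float | None,
    parent_ec50_nm: float,
    censored: bool = False,
) -> str:
    """Classify an analog by fold potency loss relative to its parent.

    Decade bins: <=3x -> ``parent_like``; (3,30]x -> ``reduced``;
    (30,300]x -> ``weak``; >300x -> ``very_weak``; out-of-range records
    -> ``censored``. Invariant under common rescaling of both EC50s.
    """
    if parent_ec50_nm <= 0 or not math.isfinite(parent_ec50_nm):
        raise ValueError("parent EC50 must be positive and finite")
    if censored or ec50_nm is None:
        return "censored"
    fold = ec50_nm / parent_ec50_nm
    if fold <= 3.0:
        return "parent_like"
    if fold <= 30.0:
        return "reduced"
    if fold <= 300.0:
        return "weak"
    return "very_weak"


def scan_series_r2(series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Squared Pearson correlation of two position-paired pEC50 series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("series must be equal-length 1-D with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


# ---------------------------------------------------------------------------
# Packaged dataset
# ---------------------------------------------------------------------------

def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("glp1qsar.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_peptide_table(path: str | None = None) -> pd.DataFrame:
    """Raw peptide potency table (one row per peptide) as a DataFrame."""
    if path is None:
        return _read_packaged_csv("tables1_3_ec50.csv")
    return pd.read_csv(path)


def load_peptide_records(path: str | None = None) -> list[PeptideRecord]:
    """Packaged (or user-supplied) peptide dataset as validated records."""
    df = load_peptide_table(path)
    records = []
    for _, row in df.iterrows():
        censored = bool(row["censored"])
        ec50 = row.get("ec50_nM")
        ec50 = None if censored or pd.isna(ec50) else float(ec50)
        emax = row.get("emax_pct")
        pec50 = row.get("pec50")
        records.append(
            PeptideRecord(
                id=str(row["id"]),
                sequence=tuple(str(row[f"pos{i}"]) for i in range(1, 12)),
                ec50_nm=ec50,
                censored=censored,
                emax_pct=None if pd.isna(emax) else float(emax),
                pec50=None if pd.isna(pec50) else float(pec50),
                series=str(row["series"]),
                in_training_31=bool(row["in_training_31"]),
            )
        )
    return records


def load_scan_pairs(path: str | None = None) -> list[ScanPair]:
    """Aib/Ala scan pair wiring (parent pair plus one pair per position)."""
    df = (_read_packaged_csv("table4_pec50.csv") if path is None
          else pd.read_csv(path))
    return [
        ScanPair(
            position=int(row["position"]),
            aib_id=str(row["aib_id"]),
            ala_id=str(row["ala_id"]),
            role=str(row["role"]),
        )
        for _, row in df.iterrows()
    ]


def load_printed_methylation_table() -> pd.DataFrame:
    """The printed per-position decomposition (for cross-checking)."""
    return _read_packaged_csv("table4_pec50.csv")


def load_potency_profile(path: str | None = None) -> pd.DataFrame:
    """Potency/efficacy profile table with per-series parent assignments."""
    df = (_read_packaged_csv("table6_profile.csv") if path is None
          else pd.read_csv(path))
    parents = df.set_index("id")["ec50_nM"].to_dict()
    classes = []
    for _, row in df.iterrows():
        censored = bool(row["censored"])
        ec50 = None if censored else float(row["ec50_nM"])
        classes.append(
            potency_class(ec50, float(parents[row["parent_id"]]), censored)
        )
    out = df.copy()
    out["potency_class"] = classes
    return out
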