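"""Gel-filtration calibration, protein mass arithmetic and stoichiometry.

This module covers the quantitative biophysics used to establish the subunit
composition of a heteromeric endolysin complex:

* size-exclusion (gel filtration, GF) column calibration from protein
  standards via the partition coefficient Kav = (Ve - V0) / (Vt - V0), with
  two linearizations -- log10(mass) linear in Kav, and sqrt(-ln Kav) linear
  in the Stokes radius (Laurent-Killander form) -- so apparent masses can be
  estimated either directly or through the Stokes radius;
* sequence-based monoisotopic/average mass and molar extinction coefficient
  (Gill-von Hippel convention) calculators;
* algebraic inversion of an electrospray charge-state series
  (M = z * m/z - z * m_proton per peak) to a mass with its spread; and
* exhaustive enumeration of integer (a FLP : b CTP) compositions against an
  observed complex mass, minimizing the absolute mass residual.

No spectral processing or deconvolution is performed: peak lists, elution
volumes and subunit masses are inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _ptm_mass
from scipy import stats

logger = logging.getLogger(__name__)

PROTON_MASS_DA = 1.00728

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Gill & von Hippel molar absorptivities at 280 nm, 1/(M*cm)
EXT_TRP = 5500.0
EXT_TYR = 1490.0
EXT_CYSTINE = 125.0

#: GF standards (name, mass kDa, Stokes radius nm) of the common calibration
#: mix: thyroglobulin, gamma-globulin, conalbumin, ovalbumin, myoglobin and
#: vitamin B12.  Elution volumes are run-specific and must come from data.
REFERENCE_GF_STANDARDS: tuple[tuple[str, float, float], ...] = (
    ("thyroglobulin", 670.0, 8.6),
    ("gamma-globulin", 158.0, 5.1),
    ("conalbumin", 75.0, 3.72),
    ("ovalbumin", 44.0, 2.73),
    ("myoglobin", 17.0, 1.91),
    ("vitamin-B12", 1.35, 0.85),
)


@dataclass
class GFStandard:
    name: str
    mass_kda: float
    stokes_radius_nm: float
    ve_ml: float


@dataclass
class CalibrationCurve:
    """Least-squares GF calibration fits over the usable standards."""

    v0_ml: float
    vt_ml: float
    mass_fit: tuple[float, float]       # log10(mass) = slope * Kav + intercept
    rs_fit: tuple[float, float]         # sqrt(-ln Kav) = slope * Rs + intercept
    rs_mass_fit: tuple[float, float]    # log10(mass) = slope * Rs + intercept
    r2_mass: float = 0.0
    r2_rs: float = 0.0


@dataclass
class StoichiometryFit:
    """Best integer (a FLP, b CTP) composition for an observed complex mass."""

    m_flp_kda: float
    m_ctp_kda: float
    observed_kda: float
    bounds: tuple[int, int]
    best: tuple[int, int]
    predicted_kda: float
    residual_kda: float  # signed, predicted - observed
    table: list[tuple[int, int, float, float]] = field(default_factory=list)
    # table rows: (a, b, predicted_kda, |residual|), ranked best-first


# ---------------------------------------------------------------------------
# gel filtration
# ---------------------------------------------------------------------------


def kav(ve: float, v0: float, vt: float) -> float:
    """Partition coefficient (Ve - V0) / (Vt - V0)."""
    if not v0 < vt:
        raise ValueError(f"void volume {v0} must be below total volume {vt}")
    if not (v0 <= ve <= vt):
        raise ValueError(
            f"elution volume {ve} outside the fractionation range [{v0}, {vt}]"
        )
    return (ve - v0) / (vt - v0)


def calibrate(
    standards: Sequence[GFStandard], v0: float, vt: float
) -> CalibrationCurve:
    """Fit the GF calibration from >= 3 usable standards.

    Standards eluting outside [v0, vt] are excluded with a warning; standards
    at Kav = 0 are excluded from the Stokes-radius fit (the -ln Kav transform
    diverges there).
    """
    usable: list[tuple[GFStandard, float]] = []
    for s in standards:
        try:
            usable.append((s, kav(s.ve_ml, v0, vt)))
        except ValueError:
            logger.warning(
                "standard %s (Ve=%.2f mL) outside fractionation range; excluded",
                s.name,
                s.ve_ml,
            )
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable standards, got {len(usable)}")

    ks = np.array([k for _, k in usable])
    logm = np.array([math.log10(s.mass_kda) for s, _ in usable])
    fit_m = stats.linregress(ks, logm)

    rs_pts = [(s.stokes_radius_nm, k) for s, k in usable if 0.0 < k <= 1.0]
    if len(rs_pts) < 3:
        raise ValueError("need >= 3 standards with 0 < Kav <= 1 for the Rs fit")
    rs = np.array([r for r, _ in rs_pts])
    y = np.sqrt(-np.log(np.array([k for _, k in rs_pts])))
    fit_rs = stats.linregress(rs, y)

    masses_rs = np.array(
        [math.log10(s.mass_kda) for s, k in usable if 0.0 < k <= 1.0]
    )
    fit_rs_mass = stats.linregress(rs, masses_rs)

    return CalibrationCurve(
        v0_ml=v0,
        vt_ml=vt,
        mass_fit=(fit_m.slope, fit_m.intercept),
        rs_fit=(fit_rs.slope, fit_rs.intercept),
        rs_mass_fit=(fit_rs_mass.slope, fit_rs_mass.intercept),
        r2_mass=fit_m.rvalue**2,
        r2_rs=fit_rs.rvalue**2,
    )


def estimate_mass(ve: float, curve: CalibrationCurve) -> float:
    """Apparent mass (kDa) from an elution volume, direct log10(mass)-Kav route."""
    k = kav(ve, curve.v0_ml, curve.vt_ml)
    slope, intercept = curve.mass_fit
    return 10.0 ** (slope * k + intercept)


def estimate_rs(ve: float, curve: CalibrationCurve) -> float:
    """Apparent Stokes radius (nm) from an elution volume."""
    k = kav(ve, curve.v0_ml, curve.vt_ml)
    if k <= 0.0:
        raise ValueError("Kav <= 0: protein elutes in the void volume")
    slope, intercept = curve.rs_fit
    return (math.sqrt(-math.log(k)) - intercept) / slope

def estimate_mass_via_rs(ve: float, curve: CalibrationCurve) -> float:
    """Apparent mass (kDa) obtained through the Stokes radius of the standards."""
    rs = estimate_rs(ve, curve)
    slope, intercept = curve.rs_mass_fit
    return 10.0 ** (slope * rs + intercept)


def estimate_all(ve: float, curve: CalibrationCurve) -> dict[str, float]:
    """Both mass routes plus the Stokes radius, reported together."""
    return {
        "mass_kda": estimate_mass(ve, curve),
        "rs_nm": estimate_rs(ve, curve),
        "mass_via_rs_kda": estimate_mass_via_rs(ve, curve),
    }


def read_standards_tsv(path: str | Path) -> list[GFStandard]:
    """Read a standards table with columns name, mass_kda, rs_nm, ve_ml."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"name", "mass_kda", "rs_nm", "ve_ml"}
    if required - set(df.columns):
        raise ValueError(f"standards table needs columns {sorted(required)}")
    return [
        GFStandard(r.name, float(r.mass_kda), float(r.rs_nm), float(r.ve_ml))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# sequence masses and extinction coefficients
# ---------------------------------------------------------------------------


def sequence_mass(protein: str, kind: str = "monoisotopic") -> float:
    """Mass in Da of an unmodified polypeptide (residues + one water)."""
    if kind not in ("monoisotopic", "average"):
        raise ValueError(f"kind must be monoisotopic or average, got {kind!r}")
    if not protein:
        raise ValueError("empty protein sequence")
    for pos, aa in enumerate(protein, start=1):
        if aa not in VALID_RESIDUES:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    return float(
        _ptm_mass.calculate_mass(sequence=protein, average=(kind == "average"))
    )


def mass_deviation(experimental: float, theoretical: float) -> float:
    """Absolute deviation (Da) between an experimental and a theoretical mass."""
    if experimental <= 0 or theoretical <= 0:
        raise ValueError("masses must be positive")
    return abs(experimental - theoretical)


def extinction_coefficient(protein: str, cystines: bool = False) -> float:
    """Molar extinction coefficient at 280 nm, 1/(M*cm), Gill-von Hippel.

    ``cystines=True`` counts each disulfide-paired Cys pair at 125 1/(M*cm)
    (assuming all cysteines are paired, floor of nC/2 pairs).
    """
    for pos, aa in enumerate(protein, start=1):
        if aa not in VALID_RESIDUES:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    eps = protein.count("W") * EXT_TRP + protein.count("Y") * EXT_TYR
    if cystines:
        eps += (protein.count("C") // 2) * EXT_CYSTINE
    return eps


# ---------------------------------------------------------------------------
# charge-state series and stoichiometry
# ---------------------------------------------------------------------------


def mass_from_csd(peaks: Iterable[tuple[float, int]]) -> tuple[float, float]:
    """Invert a charge-state series to (mean mass, sd) in Da.

    Each (m/z, z) peak gives M = z * m/z - z * m_H+; the spread across peaks
    is the population standard deviation (0 for a single peak).
    """
    peaks = list(peaks)
    if not peaks:
        raise ValueError("need at least one (m/z, z) peak")
    masses = []
    for mz, z in peaks:
        if z <= 0:
            raise ValueError(f"charge must be a positive integer, got {z}")
        masses.append(z * mz - z * PROTON_MASS_DA)
    arr = np.asarray(masses)
    return float(arr.mean()), float(arr.std(ddof=0))


def complex_mass(a: int, b: int, m_flp: float, m_ctp: float) -> float:
    """Mass of an (a FLP + b CTP) complex, same units as the subunit masses."""
    if a < 0 or b < 0:
        raise ValueError("subunit counts must be non-negative")
    if a == 0 and b == 0:
        raise ValueError("empty composition")
    return a * m_flp + b * m_ctp


def best_stoichiometry(
    observed: float,
    m_flp: float,
    m_ctp: float,
    a_max: int = 3,
    b_max: int = 10,
) -> StoichiometryFit:
    """Exhaustively enumerate compositions and pick the closest to *observed*.

    All (a, b) with 0 <= a <= a_max, 0 <= b <= b_max, (a, b) != (0, 0) are
    scored by |a*m_flp + b*m_ctp - observed|; ties break to smaller a then
    smaller b.  The full ranked table is kept on the result.
    """
    if observed <= 0:
        raise ValueError("observed mass must be positive")
    if a_max < 1 or b_max < 1:
        raise ValueError("bounds must be at least (1, 1)")
    rows: list[tuple[int, int, float, float]] = []
    for a in range(a_max + 1):
        for b in range(b_max + 1):
            if a == 0 and b == 0:
                continue
            pred = complex_mass(a, b, m_flp, m_ctp)
            rows.append((a, b, pred, abs(pred - observed)))
    rows.sort(key=lambda r: (r[3], r[0], r[1]))
    a, b, pred, _ = rows[0]
    return StoichiometryFit(
        m_flp_kda=m_flp,
        m_ctp_kda=m_ctp,
        observed_kda=observed,
        bounds=(a_max, b_max),
        best=(a, b),
        predicted_kda=pred,
        residual_kda=pred - observed,
        table=rows,
    )
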