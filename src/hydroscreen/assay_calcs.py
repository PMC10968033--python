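"""Wet-assay calculus: protein content/yield, OPA serine equivalents, DH%, glycine equivalents.

DH% (degree of hydrolysis) is derived from an OPA microplate read-out via an
L-serine calibration line; peptide concentration for SPR is expressed in mM
glycine equivalents via a glycine calibration line. Negative concentration
results are errors, never silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import mean, stdev
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "OPAWell",
    "OPAPlate",
    "fit_calibration",
    "serine_equivalents",
    "dh_percent",
    "dh_from_plate",
    "protein_and_yield",
    "glycine_equivalents",
    "read_calibration_csv",
    "read_plate_csv",
]

#: nitrogen → protein conversion factor (DUMAS)
NITROGEN_PROTEIN_FACTOR = 6.25


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    analyte: str = "serine"
    abs_range: tuple[float, float] | None = None  # calibrant absorbance span

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class OPAWell:
    sample_id: str
    dilution_factor: int
    absorbance_340: float
    replicate: int

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class OPAPlate:
    wells: tuple[OPAWell, ...]
    blank_absorbance: float

    def __post_init__(self) -> None:
        seen = set()
        for w in self.wells:
            key = (w.sample_id, w.dilution_factor, w.replicate)
            if key in seen:
                raise ValueError(f"duplicate well {key}")
            seen.add(key)


def fit_calibration(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    analyte: str = "serine",
) -> CalibrationCurve:
    """Ordinary least-squares calibration line over ≥3 points."""
    conc = np.asarray(concentrations, dtype=float)
    ab = np.asarray(absorbances, dtype=float)
    if conc.size != ab.size:
        raise ValueError("concentration/absorbance length mismatch")
    if conc.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(conc) == 0:
        raise ValueError("singular design: all concentrations equal")
    res = stats.linregress(conc, ab)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        analyte=analyte,
        abs_range=(float(ab.min()), float(ab.max())),
    )


def serine_equivalents(
    abs_sample: float,
    abs_blank: float,
    curve: CalibrationCurve,
    df: int,
) -> float:
    """Serine-equivalent concentration (mg Ser/mL) from a blank-corrected absorbance.

    ((abs_sample - abs_blank - intercept) / slope) * DF; a negative result is
    an error (absorbance below the blank/calibration floor).
    """
    if df < 1:
        raise ValueError("dilution factor must be >= 1")
    value = (abs_sample - abs_blank - curve.intercept) / curve.slope * df
    if value < 0:
        raise ValueError(
            f"negative concentration ({value:.4g}): absorbance below "
            "blank/calibration floor"
        )
    return value


def dh_percent(serine_eq: float, protein_pct: float) -> float:
    """Degree of hydrolysis (%) from serine equivalents and protein content (% w/v)."""
    if protein_pct <= 0:
        raise ValueError("protein content must be positive")
    return serine_eq / (protein_pct * 10.0) * 100.0


def dh_from_plate(
    plate: OPAPlate,
    curve: CalibrationCurve,
    protein_pct_by_sample: Mapping[str, float],
) -> dict[str, tuple[float, float]]:
    """Per-sample DH% mean ± sd over in-range wells.

    Wells whose blank-corrected absorbance falls outside the calibration
    absorbance span (e.g. saturated wells) are excluded; a sample with no
    in-range well raises.
    """
    per_sample: dict[str, list[float]] = {}
    for well in plate.wells:
        pct = protein_pct_by_sample.get(well.sample_id)
        if pct is None:
            raise KeyError(f"no protein content for sample {well.sample_id!r}")
        corrected = well.absorbance_340 - plate.blank_absorbance
        if curve.abs_range is not None:
            lo, hi = curve.abs_range
            if not lo <= corrected <= hi:
                continue  # saturated or below range: excluded
        ser = serine_equivalents(
            well.absorbance_340, plate.blank_absorbance, curve, well.dilution_factor
        )
        per_sample.setdefault(well.sample_id, []).append(dh_percent(ser, pct))
    out = {}
    for sample in protein_pct_by_sample:
        values = per_sample.get(sample)
        if not values:
            raise ValueError(f"no wells within calibration range for {sample!r}")
        sd = stdev(values) if len(values) > 1 else 0.0
        out[sample] = (mean(values), sd)
    return out


def protein_and_yield(
    dumas_pct: float,
    supernatant_g: float,
    protafy_g: float,
    purity: float | None = None,
) -> tuple[float, float]:
    """Supernatant protein mass (g) and protein yield (%).

    protein_g = dumas_pct/100 * supernatant_g; yield divides by the raw
    substrate mass, or by substrate * purity when a protein-basis purity
    (e.g. 0.84) is supplied.
    """
    if supernatant_g <= 0 or protafy_g <= 0:
        raise ValueError("masses must be positive")
    protein_g = dumas_pct / 100.0 * supernatant_g
    denom = protafy_g * purity if purity is not None else protafy_g
    return protein_g, protein_g / denom * 100.0


def glycine_equivalents(
    abs_sample: float, abs_blank: float, curve: CalibrationCurve
) -> float:
    """Peptide concentration in mM glycine equivalents (undiluted protocol, DF = 1)."""
    value = (abs_sample - abs_blank - curve.intercept) / curve.slope
    if value < 0:
        raise ValueError(
            f"negative concentration ({value:.4g}): absorbance below "
            "blank/calibration floor"
        )
    return value


def read_calibration_csv(path: str | Path, analyte: str = "serine") -> CalibrationCurve:
    """Fit a calibration line from a CSV with columns concentration, absorbance."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return fit_calibration(df["concentration"], df["absorbance"], analyte=analyte)


def read_plate_csv(path: str | Path, blank_absorbance: float | None = None) -> OPAPlate:
    """Read an OPA plate CSV with columns sample, df, replicate, absorbance.

    The blank may be given as rows with sample == "blank" (averaged) or via
    the ``blank_absorbance`` argument.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    blanks = df[df["sample"].str.lower() == "blank"]
    rest = df[df["sample"].str.lower() != "blank"]
    if blank_absorbance is None:
        if blanks.empty:
            raise ValueError("no blank rows and no blank_absorbance given")
        blank_absorbance = float(blanks["absorbance"].mean())
    wells = tuple(
        OPAWell(
            sample_id=str(r.sample),
            dilution_factor=int(r.df),
            absorbance_340=float(r.absorbance),
            replicate=int(r.replicate),
        )
        for r in rest.itertuples(index=False)
    )
    return OPAPlate(wells=wells, blank_absorbance=blank_absorbance)
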