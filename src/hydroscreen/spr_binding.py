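"""SPR sorption isotherms and 1:1 (Langmuir) binding-model fits.

The equilibrium response R at analyte concentration C under the 1:1 model is

    R(C) = R_max * C / (K_D + C)

Fits run on the linear response scale with unweighted residuals; duplicate
concentrations enter as separate residuals. Standard errors come from the
residual-variance-scaled inverse curvature at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Isotherm",
    "BindingFit",
    "double_reference",
    "equilibrium_response",
    "fit_langmuir",
    "saturation_check",
    "read_isotherm_csv",
    "write_isotherm_csv",
]


@dataclass(frozen=True)
class Isotherm:
    """Concentration-response pairs for one sample; duplicates allowed."""

    points: tuple[tuple[float, float], ...]  # (concentration, response RU)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _ in self.points):
            raise ValueError("concentrations must be positive")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def responses(self) -> np.ndarray:
        return np.array([r for _, r in self.points])

    @property
    def cmax(self) -> float:
        return float(self.concentrations.max())


@dataclass(frozen=True)
class BindingFit:
    kd: float
    rmax: float
    se_kd: float
    se_rmax: float
    residual_sse: float
    cmax: float
    saturation_flag: bool = False
    note: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("fitted K_D must be positive")
        if self.rmax < 0:
            raise ValueError("fitted R_max must be non-negative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def double_reference(
    active: Sequence[float],
    reference: Sequence[float],
    blank_before: Sequence[float],
    blank_after: Sequence[float],
    blank_before_reference: Sequence[float] | None = None,
    blank_after_reference: Sequence[float] | None = None,
) -> np.ndarray:
    """Double-referenced SPR signal.

    corrected = (active - reference) - mean(blank_before - its reference,
    blank_after - its reference), pointwise. Blank reference series default
    to zero (blanks already reference-subtracted).
    """
    act = np.asarray(active, dtype=float)
    ref = np.asarray(reference, dtype=float)
    bb = np.asarray(blank_before, dtype=float)
    ba = np.asarray(blank_after, dtype=float)
    bbr = np.zeros_like(bb) if blank_before_reference is None else np.asarray(
        blank_before_reference, dtype=float
    )
    bar = np.zeros_like(ba) if blank_after_reference is None else np.asarray(
        blank_after_reference, dtype=float
    )
    shapes = {act.shape, ref.shape, bb.shape, ba.shape, bbr.shape, bar.shape}
    if len(shapes) != 1:
        raise ValueError(f"series length mismatch: {sorted(shapes)}")
    return (act - ref) - 0.5 * ((bb - bbr) + (ba - bar))


def equilibrium_response(
    corrected: Sequence[float],
    times: Sequence[float],
    association_end: float,
    tail_seconds: float = 10.0,
    association_start: float = 0.0,
) -> float:
    """Mean corrected RU over the final ``tail_seconds`` of the association window."""
    if tail_seconds <= 0:
        raise ValueError("tail_seconds must be positive")
    if association_end - association_start < tail_seconds:
        raise ValueError("tail longer than association window")
    y = np.asarray(corrected, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("corrected/times length mismatch")
    mask = (t >= association_end - tail_seconds) & (t <= association_end)
    if not mask.any():
        raise ValueError("no samples in the tail window")
    return float(y[mask].mean())


def _langmuir(c: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    return rmax * c / (kd + c)


def fit_langmuir(
    isotherm: Isotherm,
    fit_offset: bool = False,
    max_iter: int = 500,
) -> BindingFit:
    """Nonlinear least-squares fit of the 1:1 binding model.

    Initialization: R_max0 = 1.1 * max response, K_D0 = concentration whose
    response is nearest R_max0 / 2. Convergence at relative parameter change
    < 1e-10 or ``max_iter`` iterations. With ``fit_offset`` a constant
    baseline is added as a third parameter (sensitivity analysis only).
    """
    c = isotherm.concentrations
    r = isotherm.responses
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.all(r <= 0):
        raise ValueError("no binding signal: all responses <= 0")

    rmax0 = 1.1 * r.max()
    kd0 = float(c[np.argmin(np.abs(r - rmax0 / 2.0))])
    x0 = [np.log(kd0), rmax0] + ([0.0] if fit_offset else [])

    def residuals(x: np.ndarray) -> np.ndarray:
        kd, rmax = np.exp(x[0]), x[1]
        offset = x[2] if fit_offset else 0.0
        return _langmuir(c, kd, rmax) + offset - r

    result = least_squares(
        residuals, x0, xtol=1e-10, ftol=1e-14, gtol=1e-14, max_nfev=max_iter * 10
    )
    if not result.success:
        raise RuntimeError(f"1:1 binding fit did not converge: {result.message}")
    kd = float(np.exp(result.x[0]))
    rmax = float(result.x[1])
    sse = float(2.0 * result.cost)

    # SEs on the (kd, rmax) scale from the Jacobian of the untransformed model
    n, p = c.size, (3 if fit_offset else 2)
    jac = np.column_stack(
        [-rmax * c / (kd + c) ** 2, c / (kd + c)]
        + ([np.ones_like(c)] if fit_offset else [])
    )
    dof = max(n - p, 1)
    sigma2 = sse / dof
    try:
        cov = sigma2 * np.linalg.inv(jac.T @ jac)
        se_kd = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_rmax = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_kd = se_rmax = float("nan")

    fit = BindingFit(
        kd=kd,
        rmax=rmax,
        se_kd=se_kd,
        se_rmax=se_rmax,
        residual_sse=sse,
        cmax=isotherm.cmax,
        sample_id=isotherm.sample_id,
    )
    return saturation_check(fit)


def saturation_check(fit: BindingFit) -> BindingFit:
    """Flag fits whose K_D exceeds half the maximum concentration tested.

    Such designs did not approach saturation, so the fitted K_D is a likely
    underestimate of the true value. Strict inequality at the boundary.
    """
    flagged = fit.kd > fit.cmax / 2.0
    note = "likely underestimation of true K_D" if flagged else ""
    return replace(fit, saturation_flag=flagged, note=note)


def read_isotherm_csv(path: str | Path, sample_id: str = "") -> Isotherm:
    """Read an isotherm CSV with columns concentration_mM_eq_gly, response_RU."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    cols = list(df.columns)
    conc_col = next((c for c in cols if c.startswith("conc")), None)
    resp_col = next((c for c in cols if c.startswith("resp")), None)
    if conc_col is None or resp_col is None:
        raise ValueError("isotherm CSV needs concentration and response columns")
    points = tuple(
        (float(c), float(r)) for c, r in zip(df[conc_col], df[resp_col])
    )
    return Isotherm(points=points, sample_id=sample_id)


def write_isotherm_csv(isotherm: Isotherm, path: str | Path) -> None:
    pd.DataFrame(
        isotherm.points, columns=["concentration_mM_eq_gly", "response_RU"]
    ).to_csv(path, index=False)
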