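"""Bacterial growth laws and proteome-compression predictions.

Fits the translation line lambda = kappa_t (phi_R - phi0) and the nutrition
line lambda = kappa_n (phi_R_max - phi_R) in the (translation-sector
fraction, relative growth rate) plane, and predicts the effect of a
gratuitous proteome fraction phi_U under two models: simple proportional
compression (phi_R scales by 1 - phi_U, growth defect -phi_U) and the
reconstructed two-line growth-law steady state (the gratuitous fraction is
subtracted from the allocatable proteome, phi_R_max -> phi_R_max - phi_U).
All growth rates are relative (wild type = 1 + s = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class SectorState:
    condition: str
    rel_growth: float  # 1 + s
    phi_r: float
    phi_u: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.phi_r <= 1):
            raise ValueError("phi_R must lie in [0, 1]")
        if self.phi_u < 0:
            raise ValueError("phi_U must be non-negative")


@dataclass
class GrowthLawFit:
    line_type: str  # "translation" | "nutrition"
    kappa: float
    phi_intercept: float  # phi0 (translation) or phi_R_max (nutrition)
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def predict(self, phi_r):
        phi_r = np.asarray(phi_r, dtype=float)
        if self.line_type == "translation":
            return self.kappa * (phi_r - self.phi_intercept)
        return self.kappa * (self.phi_intercept - phi_r)


def _states_to_arrays(states) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lam = np.array([s.rel_growth for s in states], dtype=float)
    phi_r = np.array([s.phi_r for s in states], dtype=float)
    phi_u = np.array([s.phi_u for s in states], dtype=float)
    return lam, phi_r, phi_u


def fit_growth_lines(states, line_type: str) -> GrowthLawFit:
    """Least-squares fit of one growth-law line to SectorState points.

    translation: lambda = kappa_t (phi_R - phi0), slope positive;
    nutrition: lambda = kappa_n (phi_R_max - phi_R), slope negative.
    """
    lam, phi_r, _ = _states_to_arrays(states)
    if len(lam) < 2:
        raise ValueError("need at least two states")
    if np.allclose(phi_r, phi_r[0]):
        raise ValueError("degenerate input: all phi_R identical")
    slope, intercept = np.polyfit(phi_r, lam, 1)
    if line_type == "translation":
        if slope <= 0:
            raise ValueError("translation line requires a positive d lambda / d phi_R")
        kappa, phi0 = slope, -intercept / slope
        fit = GrowthLawFit("translation", float(kappa), float(phi0), np.array([]))
    elif line_type == "nutrition":
        if slope >= 0:
            raise ValueError("nutrition line requires a negative d lambda / d phi_R")
        kappa, phimax = -slope, intercept / -slope
        fit = GrowthLawFit("nutrition", float(kappa), float(phimax), np.array([]))
    else:
        raise ValueError(f"unknown line type {line_type!r}")
    fit.residuals = lam - fit.predict(phi_r)
    return fit


def classify_line(states) -> str:
    """Sign of d lambda / d phi_R classifies the trajectory."""
    lam, phi_r, _ = _states_to_arrays(states)
    slope = np.polyfit(phi_r, lam, 1)[0]
    return "translation" if slope > 0 else "nutrition"


def growth_law_state(
    translation_fit: GrowthLawFit, nutrition_fit: GrowthLawFit, phi_u: float = 0.0
) -> tuple[float, float]:
    """Steady state (phi_R, lambda) at the intersection of the two lines.

    A gratuitous fraction phi_U reduces the allocatable proteome:
    phi_R_max -> phi_R_max - phi_U. Solved in closed form for the linear
    lines; a numeric root find on the same system is used as an internal
    consistency check elsewhere.
    """
    kt, phi0 = translation_fit.kappa, translation_fit.phi_intercept
    kn, phimax = nutrition_fit.kappa, nutrition_fit.phi_intercept
    phimax_eff = phimax - phi_u
    if phimax_eff <= phi0:
        raise ValueError("no feasible state: phi_U >= phi_R_max - phi0")
    phi_r = (kt * phi0 + kn * phimax_eff) / (kt + kn)
    lam = kt * (phi_r - phi0)
    return float(phi_r), float(lam)


def growth_law_state_numeric(
    translation_fit: GrowthLawFit, nutrition_fit: GrowthLawFit, phi_u: float = 0.0
) -> tuple[float, float]:
    """Root-find version of :func:`growth_law_state` (solver cross-check)."""
    kt, phi0 = translation_fit.kappa, translation_fit.phi_intercept
    kn, phimax = nutrition_fit.kappa, nutrition_fit.phi_intercept

    def gap(phi_r):
        return kt * (phi_r - phi0) - kn * (phimax - phi_u - phi_r)

    phi_r = optimize.brentq(gap, phi0, phimax - phi_u)
    return float(phi_r), float(kt * (phi_r - phi0))


def predict_compression(
    phi_u: float,
    model: str = "proportional",
    translation_fit: GrowthLawFit | None = None,
    nutrition_fit: GrowthLawFit | None = None,
) -> dict:
    """Predicted translation-sector factor and growth defect for phi_U.

    proportional: phi_R factor 1 - phi_U, delta_s = -phi_U.
    growth_law: two-line steady state with phi_R_max reduced by phi_U
    (growth-law model, reconstructed); delta_s is the relative growth change
    lambda(phi_U)/lambda(0) - 1.
    """
    if phi_u < 0:
        raise ValueError("phi_U must be non-negative")
    if model == "proportional":
        return {"phi_r_factor": 1.0 - phi_u, "delta_s": -phi_u, "model": model}
    if model != "growth_law":
        raise ValueError(f"unknown model {model!r}")
    if translation_fit is None or nutrition_fit is None:
        raise ValueError("growth_law model needs both line fits")
    phi_r0, lam0 = growth_law_state(translation_fit, nutrition_fit, 0.0)
    phi_r1, lam1 = growth_law_state(translation_fit, nutrition_fit, phi_u)
    return {
        "phi_r_factor": phi_r1 / phi_r0,
        "delta_s": lam1 / lam0 - 1.0,
        "model": "growth_law (reconstructed)",
    }


def trajectory_report(states) -> pd.DataFrame:
    """Per-series slopes in the (phi_U, phi_R) and (phi_U, delta_s) planes.

    Fits least-squares lines against phi_U, with t-based 95% CIs, and flags
    whether the one-to-one slope of -1 lies inside each CI.
    """
    lam, phi_r, phi_u = _states_to_arrays(states)
    if len(np.unique(phi_u)) < 2:
        raise ValueError("need at least two distinct phi_U values")
    rows = []
    for name, y in (("phi_r", phi_r), ("delta_s", lam - 1.0)):
        res = stats.linregress(phi_u, y)
        n = len(phi_u)
        if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
            t = stats.t.ppf(0.975, n - 2)
            lo, hi = res.slope - t * res.stderr, res.slope + t * res.stderr
        else:
            lo = hi = res.slope
        rows.append(
            {
                "plane": name,
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "covers_minus_one": bool(lo - 1e-12 <= -1.0 <= hi + 1e-12),
            }
        )
    return pd.DataFrame(rows)
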