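"""Flexural rigidity of the head-capsule cuticle and its deformation proxies.

The head capsule is treated as a thin plate in bending, for which the
relevant stiffness is the flexural rigidity

    D = E_I · T_hc³ / (12 (1 − ν²))        [mN·mm],

with E_I the indentation modulus (GPa), T_hc the mean cuticle thickness
(μm) and ν the Poisson ratio (default 0.3).  Two proxies describe the
mechanical demand of biting: the absolute-deformation proxy κ = F_b / D
(mm⁻¹) and the strain proxy κ̂ = κ / T_hc (mm⁻²).  Both are proportional to
the true deflection and strain up to a missing head-dimension length scale,
so they are reported with explicit units and never converted to strain
percent.

Because modulus and thickness samples are unpaired and small, they are
regressed on cuticle brightness (log10–log10 OLS) and the regressions
predict the two quantities for every ant in the bite-force cohort.  Ratio
statements over a brightness interval are intercept-free: with slopes s_E
and s_T, D(b_lo)/D(b_hi) = (b_lo/b_hi)^(s_E + 3 s_T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import LogLogFit, loglog_ols
from .units import GPA_UM3_TO_MN_MM, UM_TO_MM

__all__ = [
    "RigidityResult",
    "ImputationModel",
    "RigidityProfile",
    "plate_constant",
    "flexural_rigidity",
    "deformation_proxies",
    "fit_imputation",
    "impute_cohort",
    "augment_cohort",
    "rigidity_ratio_from_slopes",
    "rigidity_profile",
    "deflection_ratio",
]


@dataclass(frozen=True)
class RigidityResult:
    D_mN_mm: float
    plate_constant: float
    nu: float
    kappa_per_mm: float | None = None
    kappa_hat_per_mm2: float | None = None


@dataclass(frozen=True)
class ImputationModel:
    """Brightness regressions used to estimate modulus and thickness."""

    modulus_fit: LogLogFit      # E_I (GPa) vs b_RGB
    thickness_fit: LogLogFit    # T_hc (μm) vs b_RGB
    brightness_range: tuple     # validity range of the fits

    def _check(self, b, extrapolate):
        lo, hi = self.brightness_range
        b = np.asarray(b, dtype=float)
        if not extrapolate and (np.any(b < lo) or np.any(b > hi)):
            raise ValueError(
                f"brightness outside the fitted validity range [{lo:.3g}, {hi:.3g}]; "
                "pass extrapolate=True to override"
            )
        return b

    def predict_modulus(self, brightness, extrapolate=False):
        return self.modulus_fit.predict(self._check(brightness, extrapolate))

    def predict_thickness(self, brightness, extrapolate=False):
        return self.thickness_fit.predict(self._check(brightness, extrapolate))


@dataclass(frozen=True)
class RigidityProfile:
    """Change of D across a brightness interval, decomposed by source."""

    b_low: float
    b_high: float
    D_ratio: float
    modulus_factor: float
    thickness_factor: float  # the cubed-thickness contribution
    nu: float


def plate_constant(nu: float = 0.3) -> float:
    """1 / (12 (1 − ν²))."""
    if not 0 <= nu < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    return 1.0 / (12.0 * (1.0 - nu**2))


def flexural_rigidity(modulus_GPa, thickness_um, nu: float = 0.3):
    """D = E_I · T_hc³ / (12 (1 − ν²)) in mN·mm (inputs GPa and μm)."""
    E = np.asarray(modulus_GPa, dtype=float)
    T = np.asarray(thickness_um, dtype=float)
    if np.any(E <= 0) or np.any(T <= 0):
        raise ValueError("modulus and thickness must be positive")
    D = plate_constant(nu) * E * T**3 * GPA_UM3_TO_MN_MM
    return D if D.ndim else float(D)


def deformation_proxies(bite_force_mN, D_mN_mm, thickness_um):
    """(κ, κ̂): κ = F_b / D in mm⁻¹ and κ̂ = κ / T_hc in mm⁻².

    F_b = 0 is allowed (both proxies zero); D must be positive.
    """
    F = np.asarray(bite_force_mN, dtype=float)
    D = np.asarray(D_mN_mm, dtype=float)
    T = np.asarray(thickness_um, dtype=float)
    if np.any(F < 0) or np.any(D <= 0) or np.any(T <= 0):
        raise ValueError("need F_b >= 0, D > 0 and T_hc > 0")
    kappa = F / D
    kappa_hat = kappa / (T * UM_TO_MM)
    if kappa.ndim:
        return kappa, kappa_hat
    return float(kappa), float(kappa_hat)


def fit_imputation(cohort: pd.DataFrame) -> ImputationModel:
    """Fit E_I(b) and T_hc(b) on the measured subsets of a cohort table.

    Rows contribute to a fit only where the quantity's provenance flag is
    ``"measured"`` and the value is present; each fit needs ≥ 3 pairs.
    """
    model_inputs = {}
    for col, label in (("modulus_GPa", "modulus"), ("thickness_mean_um", "thickness")):
        flag = cohort.get(col + "_flag", pd.Series("measured", index=cohort.index))
        sel = (flag == "measured") & cohort[col].notna() & cohort["brightness"].notna()
        if sel.sum() < 3:
            raise ValueError(f"fewer than 3 measured {label} values; cannot fit")
        model_inputs[label] = (cohort.loc[sel, "brightness"], cohort.loc[sel, col])
    b_all = np.concatenate([np.asarray(v[0], dtype=float) for v in model_inputs.values()])
    return ImputationModel(
        modulus_fit=loglog_ols(*model_inputs["modulus"]),
        thickness_fit=loglog_ols(*model_inputs["thickness"]),
        brightness_range=(float(b_all.min()), float(b_all.max())),
    )


def impute_cohort(cohort: pd.DataFrame, model: ImputationModel,
                  extrapolate: bool = True) -> pd.DataFrame:
    """Fill missing modulus/thickness from each ant's measured brightness,
    setting the provenance flags of filled values to ``"imputed"``."""
    df = cohort.copy()
    for col, predict in (
        ("modulus_GPa", model.predict_modulus),
        ("thickness_mean_um", model.predict_thickness),
    ):
        flag_col = col + "_flag"
        if flag_col not in df:
            df[flag_col] = np.where(df[col].notna(), "measured", "missing")
        fill = df[col].isna() & df["brightness"].notna()
        if fill.any():
            df.loc[fill, col] = predict(df.loc[fill, "brightness"], extrapolate=extrapolate)
            df.loc[fill, flag_col] = "imputed"
    return df


def augment_cohort(cohort: pd.DataFrame, nu: float = 0.3) -> pd.DataFrame:
    """Add D, κ and κ̂ columns to a cohort with complete modulus/thickness."""
    df = cohort.copy()
    D = flexural_rigidity(df["modulus_GPa"].to_numpy(),
                          df["thickness_mean_um"].to_numpy(), nu=nu)
    kappa, kappa_hat = deformation_proxies(
        df["bite_force_mN"].to_numpy(), D, df["thickness_mean_um"].to_numpy()
    )
    df["D_mN_mm"] = D
    df["kappa_per_mm"] = kappa
    df["kappa_hat_per_mm2"] = kappa_hat
    return df


def rigidity_ratio_from_slopes(slope_modulus: float, slope_thickness: float,
                               b_low: float, b_high: float):
    """Shared closed form for all intercept-free ratio statements.

    Returns ``(D_ratio, modulus_factor, thickness_factor)`` where each factor
    is the change from b_high (bright) to b_low (dark):
    factor = (b_low/b_high)^slope, and D_ratio is their product with the
    thickness slope tripled.
    """
    if not (0 < b_low < b_high):
        raise ValueError("need 0 < b_low < b_high (dark to bright)")
    r = b_low / b_high
    modulus_factor = r**slope_modulus
    thickness_factor = r ** (3.0 * slope_thickness)
    return modulus_factor * thickness_factor, modulus_factor, thickness_factor


def rigidity_profile(model: ImputationModel, b_low: float = 0.13,
                     b_high: float = 0.52, nu: float = 0.3,
                     extrapolate: bool = False) -> RigidityProfile:
    """Factor change of D from the brightest (b_high) to the darkest (b_low)
    cuticle, decomposed into its modulus and cubed-thickness contributions.
    Ratios cancel the regression intercepts, so the result is anchor-free."""
    model._check([b_low, b_high], extrapolate)
    D_ratio, mf, tf = rigidity_ratio_from_slopes(
        model.modulus_fit.slope, model.thickness_fit.slope, b_low, b_high
    )
    return RigidityProfile(b_low=b_low, b_high=b_high, D_ratio=D_ratio,
                           modulus_factor=mf, thickness_factor=tf, nu=nu)


def deflection_ratio(model: ImputationModel, b_callow: float = 0.50,
                     b_forager: float = 0.15, nu: float = 0.3,
                     extrapolate: bool = False) -> float:
    """Deflection of the callow plate relative to the forager plate under
    equal load and planform: deflection ∝ 1/D, so the ratio equals
    D(b_forager)/D(b_callow) — identical to the rigidity-profile closed form
    over the same interval."""
    model._check([b_forager, b_callow], extrapolate)
    if not b_forager < b_callow:
        raise ValueError("forager brightness must be below callow brightness")
    D_ratio, _, _ = rigidity_ratio_from_slopes(
        model.modulus_fit.slope, model.thickness_fit.slope, b_forager, b_callow
    )
    return float(D_ratio)
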