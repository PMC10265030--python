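"""Synthetic cohorts, voxel phantoms, indentation traces and leaf populations.

This module emulates the statistical structure of the study system — small
*Atta vollenweideri* workers sampled from callow to forager stage — so that
every downstream analysis stage can be exercised without animals, scans or
indentation hardware.  Calibration constants are the published group-level
values: cuticle brightness 0.37 ± 0.04 one day post eclosion falling to
0.24 ± 0.04 at five days; observed brightness range 0.13–0.52; forager
anchors 7.2 GPa indentation modulus and 31.0 μm mean head-capsule thickness
at mean brightness 0.17; brightness power-law slopes −0.50 (modulus) and
−0.62 (thickness); bite force ∝ muscle volume^1.64 with scatter giving
R² ≈ 0.85; and a leaf cutting-force population with median 82 mN spanning
7–828 mN.

All positive quantities carry multiplicative lognormal noise (mean 1), which
keeps them positive and makes the log10 OLS model of the analysis exact.
Worker age is generator-internal metadata: an exponential decay through the
two printed day anchors links brightness to age, but no analysis stage uses
age directly, mirroring the study design (brightness is the observable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .indentation import (
    DIAMOND_E_GPA,
    DIAMOND_NU,
    EPSILON_BERKOVICH,
    IDEAL_BERKOVICH,
    IndentationTrace,
    TipAreaFunction,
)
from .thickness import VoxelVolume

__all__ = [
    "CohortParams",
    "AntRecord",
    "LeafPopulation",
    "DAY_ANCHORS",
    "SENSOR_NOISE_UN",
    "generate_cohort",
    "generate_age_groups",
    "generate_shell_phantom",
    "generate_indentation_trace",
    "generate_leaf_population",
    "mask_unpaired",
]

#: (age d, mean brightness, SD) for the known-age calibration ants
DAY_ANCHORS = ((1.0, 0.37, 0.04), (5.0, 0.24, 0.04))

#: typical load-cell noise of the simulated indenter (μN)
SENSOR_NOISE_UN = 1.0

_COLONIES = ("D", "E", "F")

#: measured quantities of one ant; provenance flag columns use these names
MEASURED_FIELDS = (
    "bite_force_mN",
    "muscle_volume_mm3",
    "cuticle_volume_mm3",
    "thickness_mean_um",
    "modulus_GPa",
)


@dataclass(frozen=True)
class CohortParams:
    """Generator calibration; defaults are the study conditions."""

    n_ants: int = 49
    seed: int = 0
    forager_fraction: float = 14.0 / 49.0
    brightness_day_anchors: tuple = DAY_ANCHORS
    brightness_range: tuple = (0.13, 0.52)
    forager_brightness: tuple = (0.17, 0.03)  # mean, SD
    bright_callow_ref: float = 0.435  # mean brightness of callows above 0.35
    modulus_slope: float = -0.50
    thickness_slope: float = -0.62
    modulus_anchor_GPa: float = 7.2  # at reference (forager-mean) brightness
    thickness_anchor_um: float = 31.0
    modulus_r2: float = 0.43
    thickness_r2: float = 0.87
    force_exponent: float = 1.64
    force_r2: float = 0.85
    force_anchor_mN: float = 102.0  # at the upper muscle-volume anchor
    muscle_volume_range: tuple = (0.08, 0.51)  # mm³ at bright/dark anchors
    cuticle_volume_range: tuple = (0.09, 0.22)  # mm³ at bright/dark anchors
    muscle_log10_sd: float = 0.17
    cuticle_log10_sd: float = 0.10
    thickness_cv_anchor: float = 0.61  # within-head thickness CV at reference brightness
    thickness_cv_slope: float = -0.264
    body_mass_mg: tuple = (4.5, 4.8, 1.2)  # callow mean, forager mean, SD
    body_mass_bounds: tuple = (3.0, 7.0)
    opening_angle_deg: tuple = (77.5, 5.5)

    def validate(self):
        lo, hi = self.brightness_range
        if not (0 < lo < hi <= 1):
            raise ValueError("brightness_range must be ordered within (0, 1]")
        for name in ("force_r2", "modulus_r2", "thickness_r2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("modulus_anchor_GPa", "thickness_anchor_um", "force_anchor_mN"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        for name in ("modulus_slope", "thickness_slope", "force_exponent"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not all(v > 0 for v in self.muscle_volume_range + self.cuticle_volume_range):
            raise ValueError("volume anchors must be positive")
        if self.n_ants < 2:
            raise ValueError("need at least 2 ants")
        return self

    def noise_free(self) -> "CohortParams":
        """All R² forced to 1 and additive scatter to zero — every fitted
        slope then equals its generating value exactly."""
        return replace(
            self, force_r2=1.0, modulus_r2=1.0, thickness_r2=1.0,
            muscle_log10_sd=0.0, cuticle_log10_sd=0.0,
        )


@dataclass(frozen=True)
class AntRecord:
    """One ant's biomechanical state (one row of the cohort table)."""

    ant_id: str
    colony: str
    stage: str  # 'callow' | 'forager'
    body_mass_mg: float
    brightness: float
    bite_force_mN: float
    opening_angle_deg: float
    muscle_volume_mm3: float
    cuticle_volume_mm3: float
    thickness_mean_um: float
    thickness_sd_um: float
    modulus_GPa: float
    flags: dict = field(default_factory=dict)  # field -> measured|imputed|missing


@dataclass(frozen=True)
class LeafPopulation:
    """Forces (mN) required to cut individual leaves."""

    cutting_forces_mN: np.ndarray
    source: str = "synthetic lognormal"


def _decay_rate(anchors):
    (t1, b1, _), (t2, b2, _) = anchors[0], anchors[-1]
    return math.log(b1 / b2) / (t2 - t1)


def brightness_to_age_days(brightness, anchors=DAY_ANCHORS) -> np.ndarray:
    """Invert the exponential brightness decay through the day anchors
    (generator-internal metadata, not used by any analysis stage)."""
    t1, b1, _ = anchors[0]
    k = _decay_rate(anchors)
    return t1 + np.log(b1 / np.asarray(brightness, dtype=float)) / k


def age_to_brightness(age_days, anchors=DAY_ANCHORS) -> np.ndarray:
    t1, b1, _ = anchors[0]
    k = _decay_rate(anchors)
    return b1 * np.exp(-k * (np.asarray(age_days, dtype=float) - t1))


def _mean_one_lognormal(rng, sigma_log10, n):
    """Multiplicative noise with E[noise] = 1 and log10-SD sigma_log10."""
    if sigma_log10 == 0:
        return np.ones(n)
    s = sigma_log10 * math.log(10.0)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)


def _residual_sigma(slope, log10_x, r2):
    """log10 residual SD giving the requested R² in expectation, given the
    realized spread of the regressor."""
    if r2 >= 1.0:
        return 0.0
    signal_var = slope**2 * np.var(log10_x)
    return math.sqrt(signal_var * (1.0 - r2) / r2)


def generate_cohort(params: CohortParams | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort of ants with the study's statistical structure.

    Returns a DataFrame, one ant per row, units encoded in the column names,
    plus a provenance flag column per measured quantity (all ``"measured"``;
    see :func:`mask_unpaired` for the study's partial availability).
    """
    params = (params or CohortParams())
    if seed is not None:
        params = replace(params, seed=seed)
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_ants
    n_forager = int(round(params.forager_fraction * n))
    n_forager = min(max(n_forager, 1), n - 1)
    stage = np.array(["forager"] * n_forager + ["callow"] * (n - n_forager))

    b_lo, b_hi = params.brightness_range
    fb_mean, fb_sd = params.forager_brightness
    brightness = np.empty(n)
    brightness[:n_forager] = np.clip(
        rng.normal(fb_mean, fb_sd, n_forager), b_lo, b_hi
    )
    brightness[n_forager:] = rng.uniform(b_lo, b_hi, n - n_forager)

    log_b = np.log10(brightness)
    log_b_ref = math.log10(fb_mean)

    # muscle and cuticle volume: power laws through the two printed anchors
    log_ratio = math.log10(fb_mean / params.bright_callow_ref)
    v_lo, v_hi = params.muscle_volume_range
    muscle_slope = math.log10(v_hi / v_lo) / log_ratio
    log_vm = (
        math.log10(v_hi)
        + muscle_slope * (log_b - log_b_ref)
        + np.log10(_mean_one_lognormal(rng, params.muscle_log10_sd, n))
    )
    muscle_volume = 10.0**log_vm

    c_lo, c_hi = params.cuticle_volume_range
    cuticle_slope = math.log10(c_hi / c_lo) / log_ratio
    cuticle_volume = 10.0 ** (
        math.log10(c_hi)
        + cuticle_slope * (log_b - log_b_ref)
        + np.log10(_mean_one_lognormal(rng, params.cuticle_log10_sd, n))
    )

    # thickness and modulus: printed slopes, scatter tuned to the printed R²
    sig_t = _residual_sigma(params.thickness_slope, log_b, params.thickness_r2)
    thickness = 10.0 ** (
        math.log10(params.thickness_anchor_um)
        + params.thickness_slope * (log_b - log_b_ref)
        + np.log10(_mean_one_lognormal(rng, sig_t, n))
    )
    sig_e = _residual_sigma(params.modulus_slope, log_b, params.modulus_r2)
    modulus = 10.0 ** (
        math.log10(params.modulus_anchor_GPa)
        + params.modulus_slope * (log_b - log_b_ref)
        + np.log10(_mean_one_lognormal(rng, sig_e, n))
    )
    thickness_cv = params.thickness_cv_anchor * (brightness / fb_mean) ** params.thickness_cv_slope
    thickness_sd = thickness_cv * thickness

    # bite force from muscle volume: the allometric core of the generator
    log_vm_realized = np.log10(muscle_volume)
    sig_f = _residual_sigma(params.force_exponent, log_vm_realized, params.force_r2)
    coeff = params.force_anchor_mN / v_hi**params.force_exponent
    bite_force = (
        coeff
        * muscle_volume**params.force_exponent
        * _mean_one_lognormal(rng, sig_f, n)
    )

    mass_c, mass_f, mass_sd = params.body_mass_mg
    mass_mean = np.where(stage == "forager", mass_f, mass_c)
    body_mass = np.clip(rng.normal(mass_mean, mass_sd), *params.body_mass_bounds)
    ang_mean, ang_sd = params.opening_angle_deg
    opening_angle = np.clip(rng.normal(ang_mean, ang_sd, n), 60.0, 95.0)

    df = pd.DataFrame(
        {
            "ant_id": [f"ant{i:03d}" for i in range(n)],
            "colony": rng.choice(_COLONIES, n),
            "stage": stage,
            "age_d": brightness_to_age_days(brightness, params.brightness_day_anchors),
            "body_mass_mg": body_mass,
            "brightness": brightness,
            "bite_force_mN": bite_force,
            "opening_angle_deg": opening_angle,
            "muscle_volume_mm3": muscle_volume,
            "cuticle_volume_mm3": cuticle_volume,
            "thickness_mean_um": thickness,
            "thickness_sd_um": thickness_sd,
            "modulus_GPa": modulus,
        }
    )
    for name in MEASURED_FIELDS:
        df[name + "_flag"] = "measured"
    # shuffle so row order carries no stage information
    df = df.sample(frac=1.0, random_state=np.random.RandomState(params.seed)).reset_index(drop=True)
    return df


def mask_unpaired(
    cohort: pd.DataFrame,
    n_modulus: int = 12,
    n_thickness: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate the study's unpaired sub-sampling: indentation moduli exist
    for only a modulus subset and tomographic thickness/volumes for a
    disjoint thickness subset; everything else becomes ``missing``."""
    df = cohort.copy()
    n = len(df)
    if n_modulus + n_thickness > n:
        raise ValueError("subsets exceed cohort size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    mod_idx = order[:n_modulus]
    thick_idx = order[n_modulus : n_modulus + n_thickness]
    keep = {
        "modulus_GPa": set(mod_idx),
        "thickness_mean_um": set(thick_idx),
        "muscle_volume_mm3": set(thick_idx),
        "cuticle_volume_mm3": set(thick_idx),
    }
    for col, rows in keep.items():
        drop = [i for i in range(n) if i not in rows]
        df.loc[drop, col] = np.nan
        df.loc[drop, col + "_flag"] = "missing"
        if col == "thickness_mean_um":
            df.loc[drop, "thickness_sd_um"] = np.nan
    return df


def generate_age_groups(n_per_group: int = 3, days=(1.0, 3.0, 5.0), seed: int = 0,
                        anchors=DAY_ANCHORS):
    """Known-age calibration groups: brightness at each age from the
    exponential decay through the day anchors plus the printed SD."""
    rng = np.random.default_rng(seed)
    sd = anchors[0][2]
    groups = []
    for d in days:
        mean = float(age_to_brightness(d, anchors))
        vals = np.clip(rng.normal(mean, sd, n_per_group), 0.01, 1.0)
        groups.append((float(d), vals))
    return groups


# ---------------------------------------------------------------------------
# voxel phantoms


def _radial_sq(shape, centre):
    idx = np.indices(shape, dtype=float)
    return sum((idx[i] - centre[i]) ** 2 for i in range(len(shape)))


def generate_shell_phantom(
    kind: str,
    *,
    outer_radius: int = 40,
    shell_thickness: int = 10,
    length: int = 100,
    thickness: int = 5,
    radius: int = 10,
    extent: int = 64,
    pad: int = 2,
    voxel_size_um: float = 1.0,
) -> VoxelVolume:
    """Rasterize a reference solid with known true thickness.

    Kinds: ``hollow_cylinder`` (outer_radius, shell_thickness, length),
    ``spherical_shell`` (outer_radius, shell_thickness), ``solid_ball``
    (radius) and ``flat_plate`` (thickness, extent — the plate spans the full
    extent × extent cross-section of an extent³ lattice).

    Voxels are included by centre position; annuli are half-open
    (inner < r ≤ outer) so a shell of thickness t spans exactly t voxel
    layers along a radial lattice line.  Metadata records the true thickness.
    """
    if kind in ("hollow_cylinder", "spherical_shell"):
        if shell_thickness < 1:
            raise ValueError("shell_thickness must be >= 1 px")
        if shell_thickness > outer_radius:
            raise ValueError("shell thicker than outer radius")
        inner = outer_radius - shell_thickness
        side = 2 * outer_radius + 1 + 2 * pad
        c = outer_radius + pad
        if kind == "hollow_cylinder":
            shape = (length + 2 * pad, side, side)
            r2 = _radial_sq(shape[1:], (c, c))
            ring = (r2 <= outer_radius**2) & (r2 > inner**2)
            data = np.zeros(shape, dtype=bool)
            data[pad : pad + length] = ring
            true_t = shell_thickness
            analytic = math.pi * (outer_radius**2 - inner**2) * length
        else:
            shape = (side, side, side)
            r2 = _radial_sq(shape, (c, c, c))
            data = (r2 <= outer_radius**2) & (r2 > inner**2)
            true_t = shell_thickness
            analytic = 4.0 / 3.0 * math.pi * (outer_radius**3 - inner**3)
    elif kind == "solid_ball":
        if radius < 1:
            raise ValueError("radius must be >= 1 px")
        side = 2 * radius + 1 + 2 * pad
        c = radius + pad
        r2 = _radial_sq((side, side, side), (c, c, c))
        data = r2 <= radius**2
        true_t = 2 * radius
        analytic = 4.0 / 3.0 * math.pi * radius**3
    elif kind == "flat_plate":
        if thickness < 1:
            raise ValueError("thickness must be >= 1 px")
        if thickness > extent - 2:
            raise ValueError("plate does not fit in the lattice with background above and below")
        data = np.zeros((extent, extent, extent), dtype=bool)
        z0 = (extent - thickness) // 2
        data[z0 : z0 + thickness] = True
        true_t = thickness
        analytic = thickness * extent * extent
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return VoxelVolume(
        data=data,
        voxel_size_um=voxel_size_um,
        provenance=f"synthetic {kind} phantom",
        meta={"true_thickness_px": true_t, "analytic_volume_px3": analytic, "kind": kind},
    )


# ---------------------------------------------------------------------------
# indentation traces


def generate_indentation_trace(
    modulus_true_GPa: float = 5.0,
    poisson_sample: float = 0.3,
    load_time_s: float = 5.0,
    hold_time_s: float = 20.0,
    unload_time_s: float = 5.0,
    peak_displacement_nm: float = 300.0,
    noise_sd_uN: float = 0.0,
    sample_rate_hz: float = 100.0,
    h_f_frac: float = 0.4,
    m: float = 1.5,
    area: TipAreaFunction = IDEAL_BERKOVICH,
    indenter_E_GPa: float = DIAMOND_E_GPA,
    indenter_nu: float = DIAMOND_NU,
    mode: str = "young",
    creep_nm: float = 0.0,
    seed: int = 0,
) -> IndentationTrace:
    """Trapezoidal displacement-controlled indent on a sample of known modulus.

    The unloading branch follows the Sneddon-type power law
    ``P = α (h − h_f)^m`` whose analytic stiffness at peak displacement is
    consistent with the requested modulus and the active tip-area function,
    so Oliver–Pharr analysis of a noise-free trace recovers
    ``modulus_true_GPa`` exactly (up to the fit tolerance).
    """
    if modulus_true_GPa <= 0 or peak_displacement_nm <= 0:
        raise ValueError("modulus and peak displacement must be positive")
    if not 0 <= h_f_frac < 1:
        raise ValueError("h_f_frac must lie in [0, 1)")
    E_s = modulus_true_GPa if mode == "young" else modulus_true_GPa * (1 - poisson_sample**2)
    inv_Er = (1 - poisson_sample**2) / E_s
    if not np.isinf(indenter_E_GPa):
        inv_Er += (1 - indenter_nu**2) / indenter_E_GPa
    E_r_GPa = 1.0 / inv_Er

    h_max = peak_displacement_nm
    h_f = h_f_frac * h_max
    h_c = h_max - EPSILON_BERKOVICH * (h_max - h_f) / m
    A_m2 = float(area(h_c)) * 1e-18
    S_si = 2.0 * (E_r_GPa * 1e9) * math.sqrt(A_m2) / math.sqrt(math.pi)  # N/m
    S = S_si * 1e-3  # μN/nm
    alpha = S / (m * (h_max - h_f) ** (m - 1.0))
    P_max = alpha * (h_max - h_f) ** m

    dt = 1.0 / sample_rate_hz
    t_load = np.arange(0.0, load_time_s, dt)
    t_hold = np.arange(load_time_s, load_time_s + hold_time_s, dt)
    t_unl = np.arange(
        load_time_s + hold_time_s, load_time_s + hold_time_s + unload_time_s + dt / 2, dt
    )
    h_load = h_max * t_load / load_time_s
    h_hold = np.full(t_hold.size, h_max)
    if creep_nm:
        h_hold = h_max + creep_nm * (t_hold - t_hold[0]) / max(hold_time_s, dt)
    h_unl = h_max * (1.0 - (t_unl - t_unl[0]) / unload_time_s)
    h_unl = np.clip(h_unl, 0.0, h_max)

    P_load = P_max * (h_load / h_max) ** 2
    P_hold = np.full(t_hold.size, P_max)
    P_unl = alpha * np.clip(h_unl - h_f, 0.0, None) ** m

    t = np.concatenate([t_load, t_hold, t_unl])
    h = np.concatenate([h_load, h_hold, h_unl])
    P = np.concatenate([P_load, P_hold, P_unl])
    if noise_sd_uN > 0:
        P = P + np.random.default_rng(seed).normal(0.0, noise_sd_uN, P.size)

    meta = {
        "modulus_true_GPa": modulus_true_GPa,
        "mode": mode,
        "poisson_sample": poisson_sample,
        "E_r_GPa": E_r_GPa,
        "S_uN_per_nm": S,
        "alpha": alpha,
        "h_f_nm": h_f,
        "m": m,
        "P_max_uN": P_max,
        "segment_bounds_s": (load_time_s, load_time_s + hold_time_s),
    }
    return IndentationTrace(time_s=t, displacement_nm=h, load_uN=P, meta=meta)


# ---------------------------------------------------------------------------
# leaf cutting-force population


def generate_leaf_population(
    n: int = 100_000,
    median_force_mN: float = 82.0,
    range_bounds_mN=(7.0, 828.0),
    seed: int = 0,
) -> LeafPopulation:
    """Lognormal cutting-force population with the printed median and range.

    The log-median equals log(median); the spread places the printed bounds
    near the 0.5th/99.5th percentiles.  The printed bounds are slightly
    asymmetric about the median on the log scale, so σ is set from the
    tighter bound; total probability mass outside the bounds stays ≤ 1%.
    A degenerate range (lo == hi == median) returns a point mass.
    """
    lo, hi = range_bounds_mN
    if not (0 < lo <= hi):
        raise ValueError("range bounds must be positive and ordered")
    if not (lo <= median_force_mN <= hi):
        raise ValueError("median must lie inside the range bounds")
    if lo == hi:
        forces = np.full(n, float(median_force_mN))
        return LeafPopulation(forces, source="degenerate point mass")
    z = norm.ppf(0.995)
    half_widths = [w for w in (math.log(hi / median_force_mN), math.log(median_force_mN / lo)) if w > 0]
    sigma = min(half_widths) / z
    rng = np.random.default_rng(seed)
    forces = median_force_mN * np.exp(rng.normal(0.0, sigma, n))
    return LeafPopulation(forces)
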