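"""Oliver–Pharr analysis of nanoindentation load–displacement traces.

A trapezoidal displacement-controlled indent (load ramp, hold, unload) is
segmented, the unloading branch is fitted with the power law
``P = α (h − h_f)^m``, the contact stiffness ``S = dP/dh`` is evaluated
analytically at peak displacement, and the reduced and sample moduli follow
from the contact depth and the tip-area function:

    h_c = h_max − ε P_max / S,     E_r = (√π / 2) · S / √A(h_c),
    1/E_r = (1 − ν_s²)/E_s + (1 − ν_i²)/E_i.

Units: displacement nm, load μN, stiffness μN/nm, moduli GPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .units import NM2_TO_M2, PA_TO_GPA, UN_PER_NM_TO_N_PER_M, UN_TO_N

__all__ = [
    "IndentationTrace",
    "TipAreaFunction",
    "UnloadingFit",
    "ModulusResult",
    "IDEAL_BERKOVICH",
    "DIAMOND_E_GPA",
    "DIAMOND_NU",
    "EPSILON_BERKOVICH",
    "segment_trace",
    "fit_unloading",
    "oliver_pharr_modulus",
    "analyze_trace",
]

#: geometry constant for the Berkovich indenter in the contact-depth formula
EPSILON_BERKOVICH = 0.75
#: diamond indenter elastic constants
DIAMOND_E_GPA = 1141.0
DIAMOND_NU = 0.07


@dataclass
class IndentationTrace:
    """Time (s), displacement (nm) and load (μN) of one indent."""

    time_s: np.ndarray
    displacement_nm: np.ndarray
    load_uN: np.ndarray
    segments: np.ndarray | None = None  # 'load' | 'hold' | 'unload'
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_nm = np.asarray(self.displacement_nm, dtype=float)
        self.load_uN = np.asarray(self.load_uN, dtype=float)
        if not (self.time_s.size == self.displacement_nm.size == self.load_uN.size):
            raise ValueError("time, displacement and load must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class TipAreaFunction:
    """Projected contact area A(h_c) in nm² as sum of c·h_c^e terms.

    The ideal Berkovich function is A = 24.5 h_c²; calibrated functions add
    lower-order terms (h, h^1/2, ...) fitted on a reference material.
    """

    terms: tuple = ((24.5, 2.0),)
    provenance: str = "ideal Berkovich"

    def __post_init__(self):
        if not self.terms or self.terms[0][0] <= 0:
            raise ValueError("leading area coefficient must be positive")

    def __call__(self, h_c_nm):
        h = np.asarray(h_c_nm, dtype=float)
        a = sum(c * h**e for c, e in self.terms)
        if np.any(a <= 0):
            raise ValueError("area function non-positive at requested depth")
        return a


IDEAL_BERKOVICH = TipAreaFunction()


@dataclass(frozen=True)
class UnloadingFit:
    alpha: float
    h_f_nm: float
    m: float
    S_uN_per_nm: float
    h_max_nm: float
    P_max_uN: float
    resid_log: float  # RMS residual of the log-space fit
    n_points: int


@dataclass(frozen=True)
class ModulusResult:
    S_uN_per_nm: float
    h_c_nm: float
    area_nm2: float
    E_r_GPa: float
    E_I_GPa: float
    hardness_GPa: float
    poisson_sample: float
    mode: str
    fit: UnloadingFit | None = None


def segment_trace(trace: IndentationTrace, rate_frac: float = 0.25) -> IndentationTrace:
    """Label samples 'load' / 'hold' / 'unload' from the displacement ramps.

    A sample belongs to a ramp when the local displacement rate exceeds
    ``rate_frac`` of the peak ramp rate; the plateau between the ramps is the
    hold.  A zero-length hold is tolerated with a warning.
    """
    t, h = trace.time_s, trace.displacement_nm
    dh = np.gradient(h, t)
    thresh = rate_frac * np.max(np.abs(dh))
    if thresh == 0:
        raise ValueError("flat displacement trace: no ramps found")
    labels = np.full(t.size, "hold", dtype=object)
    i_peak = int(np.argmax(h))
    labels[: i_peak + 1][dh[: i_peak + 1] > thresh] = "load"
    labels[i_peak:][dh[i_peak:] < -thresh] = "unload"
    # enforce contiguity: load ends at last loading index, unload starts at first
    load_idx = np.flatnonzero(labels == "load")
    unload_idx = np.flatnonzero(labels == "unload")
    if load_idx.size == 0 or unload_idx.size == 0:
        raise ValueError("could not identify load and unload ramps")
    labels[: load_idx[-1] + 1] = "load"
    labels[unload_idx[0] :] = "unload"
    n_hold = int(np.sum(labels == "hold"))
    if n_hold <= 2:
        labels[labels == "hold"] = "load"
        warnings.warn("no hold plateau found; trace has only two segments")
    out = IndentationTrace(t, h, trace.load_uN, segments=np.asarray(labels), meta=dict(trace.meta))
    return out


def fit_unloading(trace: IndentationTrace, window=(0.20, 0.95)) -> UnloadingFit:
    """Fit ``P = α (h − h_f)^m`` to the unloading branch.

    The fit uses the samples whose load lies in ``window`` (fractions of the
    peak load on the unloading branch, default top 20–95% to avoid
    final-contact-loss artefacts), linear least squares in log space with a
    one-dimensional search over the residual depth ``h_f``.
    """
    if trace.segments is None:
        trace = segment_trace(trace)
    sel = trace.segments == "unload"
    h = trace.displacement_nm[sel]
    P = trace.load_uN[sel]
    if h.size < 10:
        raise ValueError("need at least 10 unloading samples")
    P_max = float(P.max())
    h_max = float(h.max())
    lo, hi = window
    use = (P >= lo * P_max) & (P <= hi * P_max) & (P > 0)
    if use.sum() < 5:
        raise ValueError("unloading fit window contains fewer than 5 samples")
    hw, Pw = h[use], P[use]
    logP = np.log(Pw)
    h_min = float(hw.min())

    def sse(h_f):
        x = np.log(hw - h_f)
        A = np.column_stack([np.ones_like(x), x])
        coef, res, *_ = np.linalg.lstsq(A, logP, rcond=None)
        pred = A @ coef
        return float(np.sum((logP - pred) ** 2))

    res = minimize_scalar(sse, bounds=(0.0, h_min * (1 - 1e-9)), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"h_f search did not converge: {res.message}")
    h_f = float(res.x)
    x = np.log(hw - h_f)
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, logP, rcond=None)
    ln_alpha, m = float(coef[0]), float(coef[1])
    alpha = float(np.exp(ln_alpha))
    S = alpha * m * (h_max - h_f) ** (m - 1.0)
    rms = float(np.sqrt(np.mean((logP - A @ coef) ** 2)))
    return UnloadingFit(alpha=alpha, h_f_nm=h_f, m=m, S_uN_per_nm=S,
                        h_max_nm=h_max, P_max_uN=P_max, resid_log=rms,
                        n_points=int(use.sum()))


def oliver_pharr_modulus(
    S_uN_per_nm: float,
    P_max_uN: float,
    h_max_nm: float,
    area: TipAreaFunction = IDEAL_BERKOVICH,
    poisson_sample: float = 0.3,
    indenter_E_GPa: float = DIAMOND_E_GPA,
    indenter_nu: float = DIAMOND_NU,
    epsilon: float = EPSILON_BERKOVICH,
    mode: str = "young",
    fit: UnloadingFit | None = None,
) -> ModulusResult:
    """Reduced and sample moduli from stiffness, peak load and depth.

    ``mode`` selects the reported indentation modulus: ``"young"`` gives the
    Young's modulus E_s from the compliance equation with the sample Poisson
    ratio; ``"plane_strain"`` gives E_s/(1 − ν_s²).  Set
    ``indenter_E_GPa=np.inf`` for the rigid-indenter limit.
    """
    if S_uN_per_nm <= 0 or P_max_uN <= 0 or h_max_nm <= 0:
        raise ValueError("S, P_max and h_max must be positive")
    h_c = h_max_nm - epsilon * P_max_uN / S_uN_per_nm
    if h_c <= 0:
        raise ValueError("contact depth <= 0: trace is over-compliant")
    A_nm2 = float(area(h_c))
    S_si = S_uN_per_nm * UN_PER_NM_TO_N_PER_M
    E_r_pa = (np.sqrt(np.pi) / 2.0) * S_si / np.sqrt(A_nm2 * NM2_TO_M2)
    E_r = E_r_pa * PA_TO_GPA
    indenter_term = 0.0 if np.isinf(indenter_E_GPa) else (1 - indenter_nu**2) / indenter_E_GPa
    inv_plane_strain = 1.0 / E_r - indenter_term
    if inv_plane_strain <= 0:
        raise ValueError("reduced modulus exceeds indenter compliance limit")
    plane_strain = 1.0 / inv_plane_strain
    if mode == "young":
        E_I = plane_strain * (1 - poisson_sample**2)
    elif mode == "plane_strain":
        E_I = plane_strain
    else:
        raise ValueError(f"unknown modulus mode {mode!r}")
    hardness = (P_max_uN * UN_TO_N) / (A_nm2 * NM2_TO_M2) * PA_TO_GPA
    return ModulusResult(
        S_uN_per_nm=S_uN_per_nm, h_c_nm=h_c, area_nm2=A_nm2, E_r_GPa=E_r,
        E_I_GPa=E_I, hardness_GPa=hardness, poisson_sample=poisson_sample,
        mode=mode, fit=fit,
    )


def analyze_trace(
    trace: IndentationTrace,
    area: TipAreaFunction = IDEAL_BERKOVICH,
    poisson_sample: float = 0.3,
    window=(0.20, 0.95),
    **op_kwargs,
) -> ModulusResult:
    """Segment, fit the unloading branch and extract the modulus."""
    labeled = segment_trace(trace) if trace.segments is None else trace
    fit = fit_unloading(labeled, window=window)
    return oliver_pharr_modulus(
        fit.S_uN_per_nm, fit.P_max_uN, fit.h_max_nm, area=area,
        poisson_sample=poisson_sample, fit=fit, **op_kwargs,
    )
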