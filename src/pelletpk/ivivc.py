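"""Time-scaling in vitro-in vivo correlation (IVIVC) machinery.

The two-step ("Levy plot") approach for a fast-absorbing, dissolution-limited
drug:

1. Deconvolve the plasma profile against the fitted two-compartment
   disposition to obtain the cumulative fraction absorbed in vivo,
   ``f_abs(t)``.  The per-step absorbed amount is the central-compartment
   mass balance: the observed concentration change plus what elimination and
   net distribution removed over the step, scaled by the apparent volume.
2. Pair the times at which the in vitro dissolution curve and the in vivo
   absorption curve reach the same fraction, and regress
   ``t_in_vitro = slope * t_in_vivo + intercept``.

Convolution (the inverse of step 1) superposes bolus disposition responses
weighted by the absorption increments and is used for model validation.
A by-product of the time scaling is an affine link between the first-order
dissolution constant ``kd`` of a formulation and the absorption constant
``ka`` to use in the oral model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dissolution import KineticFit, invert_release
from .pk import ConcTimeSeries, PKParams, oral_conc, peripheral_conc

__all__ = [
    "AbsorptionProfile",
    "TimeScaling",
    "KaKdLink",
    "SOBREROL_TIME_SCALING",
    "SOBREROL_KA_KD_LINK",
    "deconvolve",
    "deconvolve_model",
    "time_scaling",
    "convolve",
    "ka_from_kd",
    "calibrate_ka_kd_link",
    "DEFAULT_FRACTION_LEVELS",
]

#: Fraction grid used to pair in vitro and in vivo times.
DEFAULT_FRACTION_LEVELS = tuple(np.round(np.arange(0.05, 0.851, 0.05), 2))

_FABS_CAP = 1.02


@dataclass
class AbsorptionProfile:
    """Cumulative fraction absorbed over time, with per-step increments."""

    times: np.ndarray
    f_abs: np.ndarray
    delta_f_abs: np.ndarray
    dose: float = 0.0  # ug

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f_abs = np.asarray(self.f_abs, dtype=float)
        self.delta_f_abs = np.asarray(self.delta_f_abs, dtype=float)
        if not (self.times.shape == self.f_abs.shape == self.delta_f_abs.shape):
            raise ValueError("times, f_abs and delta_f_abs must have equal length")
        if np.any(np.diff(self.f_abs) < -1e-12):
            raise ValueError("f_abs must be non-decreasing")
        if np.any(self.f_abs < 0) or np.any(self.f_abs > _FABS_CAP + 1e-12):
            raise ValueError(f"f_abs must lie in [0, {_FABS_CAP}]")
        if not np.allclose(np.cumsum(self.delta_f_abs), self.f_abs, atol=1e-9):
            raise ValueError("f_abs must equal the cumulative sum of delta_f_abs")


@dataclass(frozen=True)
class TimeScaling:
    """Affine map t_in_vitro = slope * t_in_vivo + intercept (h)."""

    slope: float
    intercept: float
    r_squared: float = np.nan
    fraction_levels: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("time-scaling slope must be > 0")

    def in_vitro_time(self, t_in_vivo: float) -> float:
        return self.slope * t_in_vivo + self.intercept


@dataclass(frozen=True)
class KaKdLink:
    """Affine link ka = slope * kd + intercept (both 1/h)."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("ka-kd link slope must be > 0")


#: Time-scaling map calibrated on the sobrerol immediate-release data.
SOBREROL_TIME_SCALING = TimeScaling(slope=0.494, intercept=-0.0904)

#: Reported affine ka-kd link for sobrerol formulations.
SOBREROL_KA_KD_LINK = KaKdLink(slope=0.478, intercept=0.0229)


def deconvolve(
    profile: ConcTimeSeries,
    params: PKParams,
    dt: float = 0.01,
) -> AbsorptionProfile:
    """Cumulative fraction absorbed from a plasma profile by mass balance.

    The profile must be densely sampled: ``dt`` may not exceed half the
    smallest sampling interval.  C1 is linearly interpolated onto the uniform
    ``dt`` grid; the peripheral concentration is propagated alongside by its
    own mass balance (trapezoidal stepping), so no peripheral measurements
    are needed.  Negative increments (noise) are floored at zero and the
    cumulative fraction is capped at 1.02.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if len(profile) < 2:
        raise ValueError("profile needs at least 2 samples")
    min_gap = float(np.min(np.diff(profile.times)))
    if dt > 0.5 * min_gap * (1.0 + 1e-9):
        raise ValueError(
            f"dt={dt} exceeds half the smallest sampling interval ({min_gap/2:g}); "
            "densify the profile (e.g. from the fitted model) first"
        )
    if profile.dose <= 0:
        raise ValueError("profile.dose must be set for deconvolution")
    t_end = float(profile.times[-1])
    n = int(round(t_end / dt))
    grid = np.linspace(0.0, t_end, n + 1)
    c1 = np.interp(grid, profile.times, profile.concentrations, left=0.0)
    return _deconvolve_dense(grid, c1, params, profile.dose)


def deconvolve_model(
    params: PKParams,
    dose: float,
    t_end: float = 8.0,
    dt: float = 0.01,
) -> AbsorptionProfile:
    """Deconvolve a model-generated dense profile (dose in ug).

    This is the first IVIVC step applied to the fitted model itself: the
    central and peripheral concentrations are both evaluated from the
    closed-form oral model, then run through the same mass-balance
    deconvolution as observed data.
    """
    n = int(round(t_end / dt))
    grid = np.linspace(0.0, t_end, n + 1)
    c1 = np.asarray(oral_conc(params, dose, grid))
    c2 = np.asarray(peripheral_conc(params, dose, grid))
    return _deconvolve_dense(grid, c1, params, dose, c2=c2)


def _deconvolve_dense(
    grid: np.ndarray,
    c1: np.ndarray,
    params: PKParams,
    dose: float,
    c2: np.ndarray | None = None,
) -> AbsorptionProfile:
    dt = grid[1] - grid[0]
    if c2 is None:
        # step the peripheral mass balance dC2/dt = k12 C1 - k21 C2
        # (trapezoidal / Crank-Nicolson update)
        c2 = np.zeros_like(c1)
        k12, k21 = params.k12, params.k21
        denom = 1.0 + 0.5 * k21 * dt
        for i in range(len(grid) - 1):
            c2[i + 1] = (
                c2[i] * (1.0 - 0.5 * k21 * dt)
                + 0.5 * k12 * dt * (c1[i] + c1[i + 1])
            ) / denom
    # per-step absorbed amount: concentration change plus elimination and
    # net distribution losses over the step, scaled to amount by Vd
    c1_mid = 0.5 * (c1[:-1] + c1[1:])
    c2_mid = 0.5 * (c2[:-1] + c2[1:])
    delta_d = (
        np.diff(c1)
        + ((params.k10 + params.k12) * c1_mid - params.k21 * c2_mid) * dt
    ) * params.Vd
    delta_f = np.concatenate([[0.0], np.maximum(delta_d, 0.0) / dose])
    f_abs = np.minimum(np.cumsum(delta_f), _FABS_CAP)
    delta_f = np.diff(np.concatenate([[0.0], f_abs]))
    return AbsorptionProfile(times=grid, f_abs=f_abs, delta_f_abs=delta_f, dose=dose)


def time_scaling(
    f_abs_curve: AbsorptionProfile,
    dissolution_fit: KineticFit,
    levels: Sequence[float] = DEFAULT_FRACTION_LEVELS,
) -> TimeScaling:
    """Levy-plot regression of in vitro dissolution time on in vivo absorption time.

    For each fraction level, the in vivo time is found by inverse
    interpolation of the absorption curve and the in vitro time by inverting
    the dissolution model in closed form; levels unattained by either curve
    are dropped (at least 3 must survive).
    """
    levels = [float(lv) for lv in levels]
    if any(not 0 < lv < 1 for lv in levels):
        raise ValueError("fraction levels must lie in (0, 1)")
    f = f_abs_curve.f_abs
    t = f_abs_curve.times
    t_vivo, t_vitro, used = [], [], []
    f_max = float(f[-1])
    for lv in levels:
        if lv >= f_max:
            continue
        t_vivo.append(float(np.interp(lv, f, t)))
        t_vitro.append(invert_release(dissolution_fit, lv))
        used.append(lv)
    if len(used) < len(levels):
        import warnings

        warnings.warn(
            f"{len(levels) - len(used)} fraction level(s) unattained and dropped",
            stacklevel=2,
        )
    if len(used) < 3:
        raise ValueError("fewer than 3 usable fraction levels for time scaling")
    res = stats.linregress(t_vivo, t_vitro)
    return TimeScaling(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fraction_levels=tuple(used),
    )


def convolve(
    absorption: AbsorptionProfile,
    params: PKParams,
    times: np.ndarray | None = None,
) -> ConcTimeSeries:
    """Plasma profile from absorption increments by superposed bolus responses.

    Each increment ``delta_f_abs(i)`` contributes a two-compartment bolus
    disposition curve launched at its onset time, scaled by
    ``dose * delta_f_abs(i) / Vd``.
    """
    if times is None:
        times = absorption.times
    times = np.asarray(times, dtype=float)
    a, b = params.alpha, params.beta
    w = absorption.dose * absorption.delta_f_abs / params.Vd
    ca = (params.k21 - a) / (b - a)
    cb = (params.k21 - b) / (a - b)
    # lag = t - onset, response only for lag >= 0
    lag = times[:, None] - absorption.times[None, :]
    active = lag >= 0
    lag = np.where(active, lag, 0.0)
    resp = ca * np.exp(-a * lag) + cb * np.exp(-b * lag)
    conc = (np.where(active, resp, 0.0) * w[None, :]).sum(axis=1)
    return ConcTimeSeries(
        times=times,
        concentrations=np.maximum(conc, 0.0),
        dose=absorption.dose,
        label="convolved",
    )


def ka_from_kd(kd: float, link: KaKdLink = SOBREROL_KA_KD_LINK) -> float:
    """Absorption constant for a formulation with dissolution constant kd."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    ka = link.slope * kd + link.intercept
    if ka <= 0:
        raise ValueError(f"link yields non-positive ka ({ka}) at kd={kd}")
    return float(ka)


def calibrate_ka_kd_link(pairs: Sequence[tuple[float, float]]) -> KaKdLink:
    """OLS fit of the affine ka-kd link from (kd, ka) pairs."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 (kd, ka) pairs")
    kd = np.array([p[0] for p in pairs], dtype=float)
    ka = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(kd) == 0:
        raise ValueError("degenerate calibration: all kd values identical")
    res = stats.linregress(kd, ka)
    return KaKdLink(slope=float(res.slope), intercept=float(res.intercept))
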