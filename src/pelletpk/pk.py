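"""Closed-form two-compartment oral pharmacokinetics with absorption lag.

The model: a first-order absorption depot feeding a central compartment that
exchanges with a peripheral compartment (rates ``k12``/``k21``) and eliminates
from the central compartment (rate ``k10``).  Plasma concentration after an
oral dose is the familiar triexponential in the hybrid macro-constants
``alpha``/``beta`` and the absorption constant ``ka``, shifted by a lag time
``tlag``.  Multiple dosing is handled by superposition; each dose's absorption
is truncated at the gastrointestinal transit time, after which the amounts
already in the body decay by pure two-compartment disposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PKParams",
    "ConcTimeSeries",
    "Regimen",
    "EfficacyIndex",
    "macro_from_micro",
    "micro_from_macro",
    "oral_conc",
    "peripheral_conc",
    "iv_disposition_conc",
    "simulate_regimen",
    "profile_metrics",
]

_DEGENERACY_TOL = 1e-9


class DegenerateParameterError(ValueError):
    """ka coincides with alpha or beta; the removable singularity is not patched."""


def macro_from_micro(k12: float, k21: float, k10: float) -> tuple[float, float]:
    """Hybrid macro-constants (alpha, beta) from the micro rate constants.

    alpha and beta are the (negated) eigenvalues of the disposition system,
    i.e. the roots of ``s^2 - (k12+k21+k10)s + k21*k10``.  alpha >= beta > 0
    whenever all micro constants are positive.
    """
    if k12 < 0 or k21 <= 0 or k10 <= 0:
        raise ValueError(
            f"rate constants must be positive (k12={k12}, k21={k21}, k10={k10})"
        )
    s = k12 + k21 + k10
    p = k21 * k10
    disc = np.sqrt(s * s - 4.0 * p)
    alpha = 0.5 * (s + disc)
    beta = p / alpha  # numerically stable: product identity alpha*beta = k21*k10
    return float(alpha), float(beta)


def micro_from_macro(alpha: float, beta: float, k21: float) -> tuple[float, float]:
    """Invert :func:`macro_from_micro` at known k21: returns (k12, k10).

    Feasibility requires alpha > k21 > beta (strict), the standard condition
    for positive k12, k10.
    """
    if not (alpha > k21 > beta > 0):
        raise ValueError(
            f"infeasible macro constants: need alpha > k21 > beta > 0, "
            f"got alpha={alpha}, k21={k21}, beta={beta}"
        )
    k10 = alpha * beta / k21
    k12 = alpha + beta - k21 - k10
    return float(k12), float(k10)


@dataclass(frozen=True)
class PKParams:
    """Parameter set of the lagged oral two-compartment model.

    Rates in 1/h, ``tlag`` in h, ``Vd`` in mL (apparent volume, Vd/F).
    ``alpha``/``beta`` are derived from the micro constants on construction.
    """

    k12: float
    k21: float
    k10: float
    ka: float
    tlag: float = 0.0
    Vd: float = 1.0
    F: float = 1.0
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "k10", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tlag < 0:
            raise ValueError(f"tlag must be >= 0, got {self.tlag}")
        if self.Vd <= 0:
            raise ValueError(f"Vd must be > 0, got {self.Vd}")
        if not (0 < self.F <= 1):
            raise ValueError(f"F must be in (0, 1], got {self.F}")
        alpha, beta = macro_from_micro(self.k12, self.k21, self.k10)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @classmethod
    def from_macro(
        cls,
        alpha: float,
        beta: float,
        k21: float,
        ka: float,
        tlag: float = 0.0,
        Vd: float = 1.0,
        F: float = 1.0,
    ) -> "PKParams":
        k12, k10 = micro_from_macro(alpha, beta, k21)
        return cls(k12=k12, k21=k21, k10=k10, ka=ka, tlag=tlag, Vd=Vd, F=F)

    def with_ka(self, ka: float) -> "PKParams":
        """Same disposition, different absorption rate (SR formulation swap)."""
        return replace(self, ka=ka)

    def _check_nondegenerate(self) -> None:
        if (
            abs(self.ka - self.alpha) < _DEGENERACY_TOL
            or abs(self.ka - self.beta) < _DEGENERACY_TOL
        ):
            raise DegenerateParameterError(
                f"ka={self.ka} coincides with a macro constant "
                f"(alpha={self.alpha}, beta={self.beta})"
            )


@dataclass
class ConcTimeSeries:
    """A sampled plasma-concentration profile (times h, concentration ug/mL)."""

    times: np.ndarray
    concentrations: np.ndarray
    dose: float = 0.0  # administered dose, ug
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be >= 0")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Regimen:
    """A dosing schedule: per-administration dose (mg) and dose times (h)."""

    dose: float
    dose_times: tuple[float, ...] = (0.0,)
    transit_time: float = 8.0
    window: float = 24.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_times", tuple(float(t) for t in self.dose_times))
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.transit_time <= 0:
            raise ValueError("transit_time must be > 0")
        if list(self.dose_times) != sorted(self.dose_times):
            raise ValueError("dose_times must be sorted")
        if any(t >= self.window for t in self.dose_times):
            raise ValueError("all dose_times must fall inside the window")

    @property
    def daily_dose(self) -> float:
        return self.dose * len(self.dose_times)


@dataclass(frozen=True)
class EfficacyIndex:
    """Cmax (ug/mL), AUC (ug*h/mL) and time above the MEC (h) of a profile."""

    cmax: float
    auc: float
    t_gt_mec: float
    mec: float


def _exp_terms(params: PKParams, tau: np.ndarray) -> np.ndarray:
    """exp(-alpha*tau), exp(-beta*tau), exp(-ka*tau) stacked; tau >= 0."""
    return np.exp(np.outer([-params.alpha, -params.beta, -params.ka], tau))


def oral_conc(params: PKParams, dose: float, t) -> np.ndarray | float:
    """Central-compartment concentration (ug/mL) after a single oral dose (ug).

    Zero for t <= tlag; triexponential in alpha, beta, ka afterwards.  Linear
    in dose.  Raises :class:`DegenerateParameterError` if ka collides with a
    macro constant.
    """
    params._check_nondegenerate()
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    tau = np.atleast_1d(t_arr) - params.tlag
    a, b, ka = params.alpha, params.beta, params.ka
    coef = np.array(
        [
            (params.k21 - a) / ((b - a) * (ka - a)),
            (params.k21 - b) / ((ka - b) * (a - b)),
            (params.k21 - ka) / ((a - ka) * (b - ka)),
        ]
    )
    pos = tau > 0
    out = np.zeros_like(tau)
    if np.any(pos):
        terms = _exp_terms(params, tau[pos])
        out[pos] = (params.ka * params.F * dose / params.Vd) * (coef @ terms)
    out = np.maximum(out, 0.0)  # guard tiny negative round-off at the lag edge
    return float(out[0]) if scalar else out


def peripheral_conc(params: PKParams, dose: float, t) -> np.ndarray | float:
    """Peripheral amount expressed on the central volume scale (ug/mL)."""
    params._check_nondegenerate()
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    tau = np.atleast_1d(t_arr) - params.tlag
    a, b, ka = params.alpha, params.beta, params.ka
    coef = np.array(
        [
            1.0 / ((b - a) * (ka - a)),
            1.0 / ((ka - b) * (a - b)),
            1.0 / ((a - ka) * (b - ka)),
        ]
    )
    pos = tau > 0
    out = np.zeros_like(tau)
    if np.any(pos):
        terms = _exp_terms(params, tau[pos])
        out[pos] = (params.ka * params.k12 * params.F * dose / params.Vd) * (
            coef @ terms
        )
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def iv_disposition_conc(
    params: PKParams,
    state_amounts: tuple[float, float],
    t_since,
) -> np.ndarray | float:
    """Central concentration decaying from arbitrary compartment amounts (ug).

    Generalizes the bolus biexponential: with a peripheral amount of zero it
    reduces to the classical ``(D/Vd)[(k21-a)/(b-a) e^{-at} + ...]`` curve, and
    from arbitrary ``(central, peripheral)`` amounts it continues an oral
    trajectory continuously after absorption is cut off.
    """
    a1_0, a2_0 = state_amounts
    if a1_0 < 0 or a2_0 < 0:
        raise ValueError("compartment amounts must be non-negative")
    t_arr = np.asarray(t_since, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise ValueError("t_since must be >= 0")
    a, b = params.alpha, params.beta
    # A1(t) = c1 e^{-at} + c2 e^{-bt} with A1(0)=a1_0 and
    # A1'(0) = -(k12+k10) a1_0 + k21 a2_0.
    da1_0 = -(params.k12 + params.k10) * a1_0 + params.k21 * a2_0
    c1 = (da1_0 + b * a1_0) / (b - a)
    c2 = a1_0 - c1
    out = (c1 * np.exp(-a * t_arr) + c2 * np.exp(-b * t_arr)) / params.Vd
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def _single_dose_profile(
    params: PKParams, dose_ug: float, transit_time: float, tau: np.ndarray
) -> np.ndarray:
    """Per-dose trajectory: oral model up to the transit cutoff, then
    disposition from the compartment amounts at the cutoff.  tau is time since
    this administration (may contain negatives, which contribute zero)."""
    out = np.zeros_like(tau)
    absorbing = (tau >= 0) & (tau <= transit_time)
    out[absorbing] = oral_conc(params, dose_ug, tau[absorbing])
    after = tau > transit_time
    if np.any(after):
        a1_cut = oral_conc(params, dose_ug, transit_time) * params.Vd
        a2_cut = peripheral_conc(params, dose_ug, transit_time) * params.Vd
        out[after] = iv_disposition_conc(
            params, (a1_cut, a2_cut), tau[after] - transit_time
        )
    return out


def simulate_regimen(
    params: PKParams,
    regimen: Regimen,
    grid_step: float = 0.01,
) -> ConcTimeSeries:
    """Superpose per-dose trajectories on a dense grid over the regimen window.

    Each administration follows the oral model for ``transit_time`` hours and
    two-compartment disposition thereafter (unabsorbed drug past the transit
    cutoff is lost).  Doses are in mg; concentrations come out in ug/mL.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if grid_step > regimen.transit_time:
        raise ValueError("grid_step must not exceed the transit time")
    n = int(round(regimen.window / grid_step))
    t = np.linspace(0.0, regimen.window, n + 1)
    dose_ug = regimen.dose * 1000.0
    conc = np.zeros_like(t)
    for td in regimen.dose_times:
        conc += _single_dose_profile(params, dose_ug, regimen.transit_time, t - td)
    return ConcTimeSeries(
        times=t,
        concentrations=conc,
        dose=dose_ug * len(regimen.dose_times),
        label=f"{regimen.dose:g} mg x{len(regimen.dose_times)}",
    )


def profile_metrics(profile: ConcTimeSeries, mec: float) -> EfficacyIndex:
    """Cmax, trapezoidal AUC, and time above the MEC with interpolated crossings."""
    if len(profile) == 0:
        raise ValueError("profile must be non-empty")
    if mec < 0:
        raise ValueError("mec must be >= 0")
    t = profile.times
    c = profile.concentrations
    cmax = float(np.max(c))
    auc = float(np.trapezoid(c, t))

    above = c > mec
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    a0, a1 = above[:-1], above[1:]
    t_gt = float(np.sum(dt[a0 & a1]))
    crossing = a0 != a1
    if np.any(crossing):
        # linear interpolation of the threshold crossing inside each step
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (mec - c0[crossing]) / (c1[crossing] - c0[crossing])
        frac = np.where(a0[crossing], s, 1.0 - s)
        t_gt += float(np.sum(dt[crossing] * frac))
    return EfficacyIndex(cmax=cmax, auc=auc, t_gt_mec=float(t_gt), mec=mec)
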