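"""Release-kinetics fitting and the f2 similarity factor.

Four standard release models are supported, all expressed on the fraction
scale f(t) in [0, 1]:

    zero_order        f = k0 * t
    first_order       f = 1 - exp(-kd * t)
    higuchi           f = kH * sqrt(t)
    korsmeyer_peppas  f = kKP * t**n

Fits are unweighted least squares in natural (untransformed) space;
log-linearization is used only to seed the nonlinear models.  The
Korsmeyer-Peppas model is, by convention, fitted on the first 60% of release
only.  The f2 similarity factor is computed on the percent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MODELS",
    "DissolutionProfile",
    "KineticFit",
    "predict_release",
    "fit_release",
    "best_model",
    "similarity_f2",
]

MODELS = ("zero_order", "first_order", "higuchi", "korsmeyer_peppas")

#: number of fitted constants per model (tie-break: prefer fewer)
_N_PARAMS = {"zero_order": 1, "first_order": 1, "higuchi": 1, "korsmeyer_peppas": 2}

_MONOTONE_TOL = 0.02


@dataclass
class DissolutionProfile:
    """Fraction-dissolved curve: times (h) and f_diss on the 0-1 scale."""

    times: np.ndarray
    f_diss: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f_diss = np.asarray(self.f_diss, dtype=float)
        if self.times.shape != self.f_diss.shape:
            raise ValueError("times and f_diss must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.f_diss < 0) or np.any(self.f_diss > 1.05):
            raise ValueError("f_diss must lie in [0, 1.05] (fraction scale)")

    def is_monotone(self, tol: float = _MONOTONE_TOL) -> bool:
        return bool(np.all(np.diff(self.f_diss) >= -tol))


@dataclass
class KineticFit:
    """A fitted release model: tag, constants, and R^2 on the fitted points."""

    model: str
    params: dict[str, float]
    r_squared: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for key, val in self.params.items():
            if key != "n" and val <= 0:
                raise ValueError(f"rate constant {key} must be > 0, got {val}")
        if self.model == "korsmeyer_peppas" and self.params.get("n", 1.0) <= 0:
            raise ValueError("korsmeyer_peppas exponent n must be > 0")


def predict_release(fit: KineticFit, t) -> np.ndarray | float:
    """Fraction dissolved at time t (h) under a fitted model; f(0) = 0."""
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    p = fit.params
    if fit.model == "zero_order":
        f = p["k0"] * t_arr
    elif fit.model == "first_order":
        f = 1.0 - np.exp(-p["kd"] * t_arr)
    elif fit.model == "higuchi":
        f = p["kH"] * np.sqrt(t_arr)
    else:  # korsmeyer_peppas
        f = p["kKP"] * t_arr ** p["n"]
    return float(f[0]) if scalar else f


def invert_release(fit: KineticFit, f: float) -> float:
    """Time (h) at which the model reaches fraction f (closed forms)."""
    if not (0 < f < 1):
        raise ValueError("f must be in (0, 1)")
    p = fit.params
    if fit.model == "zero_order":
        return f / p["k0"]
    if fit.model == "first_order":
        return -np.log1p(-f) / p["kd"]
    if fit.model == "higuchi":
        return (f / p["kH"]) ** 2
    return (f / p["kKP"]) ** (1.0 / p["n"])


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_release(
    profile: DissolutionProfile,
    model: str,
    kp_release_cap: float = 0.6,
) -> KineticFit:
    """Least-squares fit of one release model to a dissolution profile.

    Fraction values above 1 are clipped to 1 for fitting (assay overshoot);
    the Korsmeyer-Peppas fit uses only points with f <= ``kp_release_cap``.
    Non-monotone profiles (beyond a 0.02 tolerance) draw a warning but are
    fitted anyway.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if len(profile.times) < 4:
        raise ValueError("need at least 4 points to fit a release model")
    if not profile.is_monotone():
        warnings.warn(
            f"dissolution profile {profile.label!r} decreases by more than "
            f"{_MONOTONE_TOL}; fitting anyway",
            stacklevel=2,
        )
    t = profile.times
    f = np.clip(profile.f_diss, 0.0, 1.0)
    if model == "korsmeyer_peppas":
        keep = f <= kp_release_cap
        if keep.sum() >= 3:
            t, f = t[keep], f[keep]

    if model == "zero_order":
        k0 = float(np.sum(f * t) / np.sum(t * t))
        fit = KineticFit("zero_order", {"k0": max(k0, 1e-12)})
    elif model == "higuchi":
        rt = np.sqrt(t)
        kh = float(np.sum(f * rt) / np.sum(t))
        fit = KineticFit("higuchi", {"kH": max(kh, 1e-12)})
    elif model == "first_order":
        # seed from log-linearization of the unreleased fraction
        frac_left = np.clip(1.0 - f, 1e-6, None)
        kd0 = max(float(-np.polyfit(t, np.log(frac_left), 1)[0]), 1e-3)
        res = least_squares(
            lambda x: (1.0 - np.exp(-x[0] * t)) - f,
            x0=[kd0],
            bounds=([1e-8], [np.inf]),
        )
        fit = KineticFit("first_order", {"kd": float(res.x[0])})
    else:
        pos = (t > 0) & (f > 0)
        if pos.sum() >= 2:
            n0, logk0 = np.polyfit(np.log(t[pos]), np.log(f[pos]), 1)
            x0 = [max(float(np.exp(logk0)), 1e-6), float(np.clip(n0, 0.05, 3.0))]
        else:
            x0 = [0.1, 0.5]
        res = least_squares(
            lambda x: x[0] * t ** x[1] - f,
            x0=x0,
            bounds=([1e-8, 1e-3], [np.inf, 5.0]),
        )
        fit = KineticFit("korsmeyer_peppas", {"kKP": float(res.x[0]), "n": float(res.x[1])})

    fit.r_squared = _r_squared(f, np.asarray(predict_release(fit, t)))
    return fit


def best_model(profile: DissolutionProfile, r2_tie_tol: float = 1e-9) -> KineticFit:
    """Fit all four models and return the best by R^2.

    Ties within ``r2_tie_tol`` are broken in favour of the model with fewer
    parameters (so an exact square-root profile reports as Higuchi rather
    than the two-parameter power law).
    """
    fits = [fit_release(profile, m) for m in MODELS]
    best = fits[0]
    for cand in fits[1:]:
        if cand.r_squared > best.r_squared + r2_tie_tol:
            best = cand
        elif (
            abs(cand.r_squared - best.r_squared) <= r2_tie_tol
            and _N_PARAMS[cand.model] < _N_PARAMS[best.model]
        ):
            best = cand
    return best


def similarity_f2(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    time_tol: float = 1e-9,
) -> float:
    """The f2 similarity factor between two dissolution profiles.

    Computed on the percent scale over the shared time points:
    ``f2 = 50 log10( 100 / sqrt(1 + mean((R - T)^2)) )``.  Identical profiles
    give 100; f2 >= 50 is the conventional similarity criterion.
    """
    idx_r, idx_t = [], []
    j = 0
    for i, tr in enumerate(reference.times):
        while j < len(test.times) and test.times[j] < tr - time_tol:
            j += 1
        if j < len(test.times) and abs(test.times[j] - tr) <= time_tol:
            idx_r.append(i)
            idx_t.append(j)
            j += 1
    if len(idx_r) < 3:
        raise ValueError("need at least 3 shared time points for f2")
    r_pct = 100.0 * reference.f_diss[idx_r]
    t_pct = 100.0 * test.f_diss[idx_t]
    msd = float(np.mean((r_pct - t_pct) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))
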