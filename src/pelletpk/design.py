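"""Translational dose design: HED conversion, MEC, PK/PD indexing and the
(kd, dose) design search for sustained-release regimens.

The design logic chains the other modules: animal doses are scaled to human
equivalent doses (HED) by the body-surface-area Km method; the minimum
effective concentration (MEC) is the simulated single-dose peak of the
highest no-effect HED; candidate sustained-release regimens get their
absorption constant from the ka-kd link and are simulated with the
gastrointestinal-transit cutoff; the duration of action t>MEC drives a
contour over (kd, dose) and a minimal-dose bisection.  A generic quadratic
response surface in three coded coating factors maps manufacturing settings
to the dissolution constant kd.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .ivivc import KaKdLink, TimeScaling, ka_from_kd
from .pk import (
    ConcTimeSeries,
    EfficacyIndex,
    PKParams,
    Regimen,
    oral_conc,
    profile_metrics,
    simulate_regimen,
)

__all__ = [
    "HEDSpec",
    "EfficacyRecord",
    "DesignGrid",
    "RSModel",
    "hed",
    "dose_times_for_frequency",
    "determine_mec",
    "inhibition_from_scores",
    "pd_correlation",
    "fabs_at_transit",
    "min_kd_for_fabs",
    "design_contour",
    "min_dose_for_efficacy",
    "compliance_summary",
    "fit_response_surface",
    "invert_response_surface",
]

#: Administration clock times (h) by daily frequency, single-day convention.
_FREQUENCY_SCHEDULES = {1: (0.0,), 2: (0.0, 12.0), 3: (0.0, 8.0, 16.0)}


@dataclass(frozen=True)
class HEDSpec:
    """Animal-to-human dose conversion input (body-surface-area method)."""

    animal_dose: float  # mg/kg per administration
    animal_km: float = 3.0  # mouse
    human_km: float = 37.0  # adult
    body_weight: float = 60.0  # kg
    frequency_per_day: int = 1

    def __post_init__(self) -> None:
        if min(self.animal_dose, self.animal_km, self.human_km, self.body_weight) <= 0:
            raise ValueError("all HED inputs must be positive")
        if self.frequency_per_day not in (1, 2, 3):
            raise ValueError("frequency_per_day must be 1, 2 or 3")


def hed(spec: HEDSpec) -> float:
    """Human equivalent dose (mg): animal_dose * (animal_Km/human_Km) * weight.

    Returns the raw (unrounded) value; round to the nearest mg for reporting.
    """
    return spec.animal_dose * spec.animal_km / spec.human_km * spec.body_weight


def dose_times_for_frequency(frequency: int) -> tuple[float, ...]:
    """Single-day administration times: 0/8/16 h (TID), 0/12 h (BID), 0 h (QD)."""
    try:
        return _FREQUENCY_SCHEDULES[frequency]
    except KeyError:
        raise ValueError("frequency must be 1, 2 or 3") from None


@dataclass
class EfficacyRecord:
    """One regimen of the dose-response study: HED, clinical score, PK indexes."""

    hed: float  # mg per administration
    frequency_per_day: int
    eae_score: tuple[float, float]  # mean, sd
    inhibition: float  # fraction vs vehicle
    indexes: EfficacyIndex | None = None
    significant: bool = False

    def __post_init__(self) -> None:
        if self.eae_score[0] < 0:
            raise ValueError("EAE score must be >= 0")
        if not -0.5 <= self.inhibition <= 1.0:
            raise ValueError("inhibition must lie in [-0.5, 1]")


def determine_mec(
    params: PKParams,
    no_effect_hed: float,
    t_search_end: float = 24.0,
) -> float:
    """MEC (ug/mL): single-dose peak concentration of the highest no-effect HED (mg).

    The peak is located on a coarse grid and refined by bounded scalar
    minimization of the negated closed-form concentration.
    """
    if no_effect_hed <= 0:
        raise ValueError("no_effect_hed must be > 0")
    dose_ug = no_effect_hed * 1000.0
    grid = np.linspace(params.tlag, t_search_end, 2001)
    conc = np.asarray(oral_conc(params, dose_ug, grid))
    i = int(np.argmax(conc))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -oral_conc(params, dose_ug, float(t)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(-res.fun)


def inhibition_from_scores(treated: float, vehicle: float) -> float:
    """Symptom inhibition as the relative clinical-score reduction vs vehicle."""
    if vehicle <= 0:
        raise ValueError("vehicle score must be > 0")
    return (vehicle - treated) / vehicle


def pd_correlation(records: Sequence[EfficacyRecord]) -> dict[str, float]:
    """R^2 of each PK efficacy index (cmax, auc, t_gt_mec) against inhibition.

    Indexes with degenerate variance are reported as NaN.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    if any(r.indexes is None for r in records):
        raise ValueError("all records must carry simulated efficacy indexes")
    inhib = np.array([r.inhibition for r in records])
    out: dict[str, float] = {}
    for name in ("cmax", "auc", "t_gt_mec"):
        x = np.array([getattr(r.indexes, name) for r in records])
        if np.ptp(x) == 0 or np.ptp(inhib) == 0:
            out[name] = float("nan")
            continue
        res = stats.linregress(x, inhib)
        out[name] = float(res.rvalue**2)
    return out


def fabs_at_transit(
    kd: float,
    scaling: TimeScaling,
    transit_in_vivo: float = 8.0,
) -> float:
    """Fraction absorbed by the transit cutoff under first-order release.

    The in vivo transit time is mapped to its in vitro equivalent by the
    time-scaling IVIVC; absorption then equals the first-order release
    attained by that scaled time: ``1 - exp(-kd * (slope*transit + intercept))``.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    t_vitro = scaling.in_vitro_time(transit_in_vivo)
    if t_vitro <= 0:
        return 0.0
    return float(1.0 - np.exp(-kd * t_vitro))


def min_kd_for_fabs(
    target_fabs: float,
    scaling: TimeScaling,
    transit_in_vivo: float = 8.0,
) -> float:
    """Smallest first-order kd reaching ``target_fabs`` by the transit cutoff."""
    if not 0 < target_fabs < 1:
        raise ValueError("target_fabs must lie in (0, 1)")
    t_vitro = scaling.in_vitro_time(transit_in_vivo)
    if t_vitro <= 0:
        raise ValueError("scaled in vitro time is non-positive")
    return float(-np.log1p(-target_fabs) / t_vitro)


@dataclass
class DesignGrid:
    """t>MEC (h) over a (kd, per-administration dose) grid at fixed frequency."""

    kd_axis: np.ndarray
    dose_axis: np.ndarray
    t_gt_mec: np.ndarray  # shape (len(kd_axis), len(dose_axis))
    reference_t: float = np.nan
    frequency: int = 2

    def __post_init__(self) -> None:
        self.kd_axis = np.asarray(self.kd_axis, dtype=float)
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        self.t_gt_mec = np.asarray(self.t_gt_mec, dtype=float)
        if self.t_gt_mec.shape != (self.kd_axis.size, self.dose_axis.size):
            raise ValueError("t_gt_mec shape must be (len(kd_axis), len(dose_axis))")
        if np.any(self.t_gt_mec < 0):
            raise ValueError("t_gt_mec entries must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.t_gt_mec, index=self.kd_axis, columns=self.dose_axis)


def _sr_regimen_metrics(
    params: PKParams,
    link: KaKdLink,
    mec: float,
    kd: float,
    dose: float,
    frequency: int,
    transit_time: float = 8.0,
    window: float = 24.0,
    grid_step: float = 0.01,
) -> EfficacyIndex:
    sr_params = params.with_ka(ka_from_kd(kd, link))
    regimen = Regimen(
        dose=dose,
        dose_times=dose_times_for_frequency(frequency),
        transit_time=transit_time,
        window=window,
    )
    profile = simulate_regimen(sr_params, regimen, grid_step=grid_step)
    return profile_metrics(profile, mec)


def design_contour(
    params: PKParams,
    link: KaKdLink,
    mec: float,
    kd_axis: Sequence[float] | None = None,
    dose_axis: Sequence[float] | None = None,
    frequency: int = 2,
    reference_t: float = np.nan,
    grid_step: float = 0.01,
) -> DesignGrid:
    """t>MEC surface over dissolution constant and per-administration dose.

    Each cell simulates a full regimen: ka from the ka-kd link, 8-h absorption
    cutoff per dose, 24-h evaluation window, then the time above the MEC.
    """
    kd_axis = (
        np.round(np.arange(0.05, 1.2001, 0.05), 10)
        if kd_axis is None
        else np.asarray(kd_axis, dtype=float)
    )
    dose_axis = (
        np.arange(100.0, 1500.1, 10.0)
        if dose_axis is None
        else np.asarray(dose_axis, dtype=float)
    )
    if kd_axis.size == 0 or dose_axis.size == 0:
        raise ValueError("axes must be non-empty")
    if np.any(kd_axis <= 0) or np.any(dose_axis <= 0):
        raise ValueError("axes must be positive")
    grid = np.empty((kd_axis.size, dose_axis.size))
    for i, kd in enumerate(kd_axis):
        # t>MEC is dose-linear in shape: simulate the unit-dose profile once
        # per kd and rescale per dose (concentration is exactly linear in dose)
        sr_params = params.with_ka(ka_from_kd(float(kd), link))
        regimen = Regimen(
            dose=1.0, dose_times=dose_times_for_frequency(frequency)
        )
        unit = simulate_regimen(sr_params, regimen, grid_step=grid_step)
        for j, dose in enumerate(dose_axis):
            scaled = ConcTimeSeries(
                times=unit.times,
                concentrations=unit.concentrations * dose,
                dose=dose * 1000.0 * frequency,
            )
            grid[i, j] = profile_metrics(scaled, mec).t_gt_mec
    return DesignGrid(
        kd_axis=kd_axis,
        dose_axis=dose_axis,
        t_gt_mec=grid,
        reference_t=reference_t,
        frequency=frequency,
    )


def min_dose_for_efficacy(
    params: PKParams,
    link: KaKdLink,
    mec: float,
    kd: float,
    frequency: int = 2,
    target_t: float = 12.8,
    dose_bounds: tuple[float, float] = (1.0, 5000.0),
    resolution: float = 1.0,
    grid_step: float = 0.01,
) -> float:
    """Smallest per-administration dose (mg) with t>MEC >= target, by bisection.

    t>MEC is non-decreasing in dose (concentrations scale linearly), so
    bisection to ``resolution`` (default 1 mg) is exact up to the grid.
    """
    lo, hi = dose_bounds

    def t_at(dose: float) -> float:
        return _sr_regimen_metrics(
            params, link, mec, kd, dose, frequency, grid_step=grid_step
        ).t_gt_mec

    if target_t <= 0:
        return lo
    if t_at(hi) < target_t:
        raise ValueError(
            f"target t>MEC={target_t} h unattainable below {hi} mg at kd={kd}"
        )
    if t_at(lo) >= target_t:
        return lo
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if t_at(mid) >= target_t:
            hi = mid
        else:
            lo = mid
    return float(np.ceil(hi / resolution) * resolution)


def compliance_summary(
    reference: Regimen,
    designed: Regimen,
) -> tuple[float, float]:
    """(frequency reduction %, daily-dose reduction %) of designed vs reference."""
    f_ref = len(reference.dose_times)
    f_new = len(designed.dose_times)
    freq_red = 100.0 * (f_ref - f_new) / f_ref
    dose_red = 100.0 * (reference.daily_dose - designed.daily_dose) / reference.daily_dose
    return float(freq_red), float(dose_red)


# ---------------------------------------------------------------------------
# Quadratic response surface for the coating design of experiments
# ---------------------------------------------------------------------------

_RS_TERMS = ("1", "A", "B", "C", "A^2", "B^2", "C^2", "AB", "AC", "BC")


@dataclass
class RSModel:
    """Full quadratic response surface in three coded factors -> kd (1/h).

    Factors (coded -1..1): A = coating weight gain %W_coat, B = HPMC/EC
    composition ratio, C = curing temperature.
    """

    coefficients: np.ndarray  # order: _RS_TERMS

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (10,):
            raise ValueError("RSModel needs exactly 10 coefficients")

    def predict(self, a, b, c) -> np.ndarray | float:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        c = np.asarray(c, dtype=float)
        x = _rs_design_matrix(a.ravel(), b.ravel(), c.ravel())
        out = x @ self.coefficients
        return float(out[0]) if out.size == 1 and a.ndim == 0 else out.reshape(a.shape)


def _rs_design_matrix(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(a), a, b, c, a * a, b * b, c * c, a * b, a * c, b * c]
    )


def fit_response_surface(doe_table: pd.DataFrame) -> RSModel:
    """OLS fit of the full quadratic surface from a coded DoE table.

    ``doe_table`` needs columns A, B, C (coded factors) and kd (response).
    Raises on rank-deficient designs, listing the aliased terms.
    """
    required = {"A", "B", "C", "kd"}
    if not required.issubset(doe_table.columns):
        raise ValueError(f"doe_table must have columns {sorted(required)}")
    if len(doe_table) < 10:
        raise ValueError("need at least 10 distinct runs for 10 coefficients")
    x = _rs_design_matrix(
        doe_table["A"].to_numpy(float),
        doe_table["B"].to_numpy(float),
        doe_table["C"].to_numpy(float),
    )
    rank = np.linalg.matrix_rank(x)
    if rank < 10:
        # identify aliased columns via QR pivoting
        _, r = np.linalg.qr(x)
        aliased = [
            _RS_TERMS[j] for j in range(10) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-8
        ]
        raise ValueError(f"rank-deficient design (rank {rank}); aliased terms: {aliased}")
    coef, *_ = np.linalg.lstsq(x, doe_table["kd"].to_numpy(float), rcond=None)
    return RSModel(coefficients=coef)


def invert_response_surface(
    model: RSModel,
    target_kd: float,
    fixed_c: float = 0.0,
    tolerance: float = 0.02,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Coded (A, B) settings achieving kd within ``tolerance`` at fixed C.

    Grid search over the coded square [-1, 1]^2; returns the admissible
    points as a DataFrame with columns A, B, kd.
    """
    axis = np.arange(-1.0, 1.0 + grid_step / 2, grid_step)
    aa, bb = np.meshgrid(axis, axis, indexing="ij")
    kd = model.predict(aa, bb, np.full_like(aa, fixed_c))
    ok = np.abs(kd - target_kd) <= tolerance
    return pd.DataFrame(
        {"A": aa[ok].ravel(), "B": bb[ok].ravel(), "kd": np.asarray(kd)[ok].ravel()}
    )
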