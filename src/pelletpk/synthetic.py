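"""Seeded generators for every input the pipeline consumes.

These emulate the study's data world: noisy two-compartment plasma profiles
at the published sampling schedule, noisy dissolution curves under any of the
four release models, coded coating DoE tables (13-run Box-Behnken or the
27-run full factorial), and the small EAE dose-response table.  Every
generator is a pure function of its parameters and seed; zero noise
reproduces the closed-form model values bit for bit.

Multiplicative noise is mean-one log-normal with coefficient of variation
equal to ``level`` (the common bioanalytical error convention); additive
noise is Gaussian with standard deviation ``level``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datasets
from .design import (
    EfficacyRecord,
    HEDSpec,
    RSModel,
    dose_times_for_frequency,
    hed,
    inhibition_from_scores,
)
from .dissolution import DissolutionProfile, KineticFit, predict_release
from .pk import ConcTimeSeries, PKParams, Regimen, oral_conc, profile_metrics, simulate_regimen

__all__ = [
    "NoiseSpec",
    "make_plasma_profile",
    "make_dissolution_profile",
    "make_doe_table",
    "make_efficacy_table",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: multiplicative (CV = level) or additive (sd = level)."""

    kind: str = "multiplicative"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative", "additive"):
            raise ValueError("kind must be 'multiplicative' or 'additive'")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.level == 0:
            return values.copy()
        rng = np.random.default_rng(self.seed)
        if self.kind == "multiplicative":
            sigma = np.sqrt(np.log1p(self.level**2))
            factor = np.exp(rng.normal(0.0, sigma, size=values.shape) - 0.5 * sigma**2)
            return values * factor
        return values + rng.normal(0.0, self.level, size=values.shape)


def make_plasma_profile(
    params: PKParams,
    dose: float,
    times: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
) -> ConcTimeSeries:
    """Noisy single-dose plasma profile (dose in mg, times in h)."""
    times = np.asarray(times, dtype=float)
    dose_ug = dose * 1000.0
    conc = np.asarray(oral_conc(params, dose_ug, times))
    conc = np.maximum(noise.apply(conc), 0.0)
    return ConcTimeSeries(
        times=times, concentrations=conc, dose=dose_ug,
        label=f"synthetic {dose:g} mg",
    )


def make_dissolution_profile(
    fit: KineticFit,
    times: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
) -> DissolutionProfile:
    """Noisy dissolution curve from a release model, clipped to [0, 1]."""
    times = np.asarray(times, dtype=float)
    f = np.asarray(predict_release(fit, times))
    f = np.clip(noise.apply(f), 0.0, 1.0)
    return DissolutionProfile(times=times, f_diss=f, label=f"synthetic {fit.model}")


def _box_behnken_3factor() -> np.ndarray:
    """The 13-run, 3-factor Box-Behnken layout: 12 edge midpoints + 1 center."""
    runs = []
    for i, j in itertools.combinations(range(3), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            row = [0.0, 0.0, 0.0]
            row[i], row[j] = si, sj
            runs.append(row)
    runs.append([0.0, 0.0, 0.0])
    return np.array(runs)


def make_doe_table(
    model: RSModel,
    design: str = "box_behnken_3factor",
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Coded DoE table (columns A, B, C, kd) from a response-surface model."""
    if design == "box_behnken_3factor":
        pts = _box_behnken_3factor()
    elif design == "full_factorial_3level":
        pts = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=3)))
    else:
        raise ValueError(f"unknown design {design!r}")
    kd = np.asarray(model.predict(pts[:, 0], pts[:, 1], pts[:, 2]))
    kd = noise.apply(kd)
    return pd.DataFrame({"A": pts[:, 0], "B": pts[:, 1], "C": pts[:, 2], "kd": kd})


def make_efficacy_table(
    seed: int = 0,
    jitter: bool = False,
    params: PKParams | None = None,
    mec: float | None = None,
) -> list[EfficacyRecord]:
    """The five-regimen EAE dose-response table with simulated PK indexes.

    Clinical scores default to the published plateau-day means; with
    ``jitter`` they are perturbed by their reported standard deviations
    (seeded).  Each record carries the Cmax/AUC/t>MEC indexes of its
    simulated human-equivalent regimen.
    """
    if params is None:
        params = datasets.SOBREROL_PK_PARAMS
    if mec is None:
        from .design import determine_mec

        mec = determine_mec(
            params,
            hed(HEDSpec(animal_dose=30.0, frequency_per_day=1)),
        )
    rng = np.random.default_rng(seed)
    vehicle_mean, vehicle_sd = datasets.EAE_VEHICLE_SCORE
    vehicle = vehicle_mean + (rng.normal(0.0, vehicle_sd) if jitter else 0.0)
    records: list[EfficacyRecord] = []
    for animal_dose, freq, mean, sd, signif in datasets.EAE_REGIMENS:
        score = mean + (rng.normal(0.0, sd) if jitter else 0.0)
        dose_mg = hed(HEDSpec(animal_dose=animal_dose, frequency_per_day=freq))
        regimen = Regimen(
            dose=dose_mg,
            dose_times=dose_times_for_frequency(freq),
            transit_time=datasets.GI_TRANSIT_TIME,
        )
        profile = simulate_regimen(params, regimen)
        records.append(
            EfficacyRecord(
                hed=dose_mg,
                frequency_per_day=freq,
                eae_score=(score, sd),
                inhibition=float(np.clip(
                    inhibition_from_scores(score, vehicle), -0.5, 1.0
                )),
                indexes=profile_metrics(profile, mec),
                significant=signif,
            )
        )
    return records
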