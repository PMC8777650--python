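"""Published sobrerol study inputs used throughout the package.

Sobrerol is an oral mucolytic (BCS class I: highly soluble, highly permeable)
under investigation for repurposing in multiple sclerosis.  The numbers here
are the printed inputs of the published human-PK / EAE-mouse study this
package models: a single-dose 300 mg plasma profile, the reconstructed
two-compartment parameter set, first-order dissolution constants of
immediate-release (IR) and sustained-release (SR) pellet formulations, the
time-scaling in vitro-in vivo map, the ka-kd linkage, and the EAE
dose-response table that anchors the pharmacodynamic side.
"""

from __future__ import annotations

import numpy as np

from .pk import ConcTimeSeries, PKParams

__all__ = [
    "SOBREROL_PK_PARAMS",
    "SOBREROL_300MG_PROFILE",
    "IR_KD",
    "SR_KD_VALUES",
    "GI_TRANSIT_TIME",
    "EAE_REGIMENS",
    "EAE_VEHICLE_SCORE",
    "MOUSE_KM",
    "HUMAN_KM",
    "HUMAN_BODY_WEIGHT",
]

#: Gastrointestinal transit time (h): the absorption window per administration.
GI_TRANSIT_TIME = 8.0

#: Body-surface-area correction factors for human-equivalent-dose conversion.
MOUSE_KM = 3.0
HUMAN_KM = 37.0
HUMAN_BODY_WEIGHT = 60.0  # kg, adult reference

# Reconstructed lagged oral two-compartment parameters for sobrerol:
# Vd = 44.94 L (apparent, Vd/F with F = 1), k12 = 0.82 /h, k21 = 0.95 /h,
# ka = 2.40 /h, tlag = 0.18 h.  k10 is back-solved from the reported hybrid
# constants alpha = 2.08 /h, beta = 0.26 /h via k10 = alpha*beta/k21.
SOBREROL_PK_PARAMS = PKParams(
    k12=0.82,
    k21=0.95,
    k10=2.08 * 0.26 / 0.95,
    ka=2.40,
    tlag=0.18,
    Vd=44940.0,  # mL
    F=1.0,
)

#: Plasma concentrations (ug/mL) after a single oral 300 mg dose.
SOBREROL_300MG_PROFILE = ConcTimeSeries(
    times=np.array([0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]),
    concentrations=np.array([1.01, 2.82, 3.77, 2.02, 1.41, 1.05, 0.63, 0.37]),
    dose=300_000.0,  # ug
    label="sobrerol 300 mg single oral dose",
)

#: First-order dissolution constant of the IR pellets (1/h).
IR_KD = 4.99

#: First-order dissolution constants (1/h) of the 13 SR pellet formulations.
SR_KD_VALUES = {
    "SR-5": 1.082,
    "SR-10": 0.978,
    "SR-1": 0.858,
    "SR-6": 0.393,
    "SR-13": 0.131,
    "SR-12": 0.115,
    "SR-7": 0.115,
    "SR-3": 0.096,
    "SR-8": 0.059,
    "SR-4": 0.048,
    "SR-2": 0.036,
    "SR-9": 0.036,
    "SR-11": 0.029,
}

#: EAE mouse dose-response: animal dose (mg/kg per administration),
#: administrations per day, and plateau-day clinical score (mean, sd).
#: Vehicle (thrice daily) scored 4.00 +/- 0.22.
EAE_VEHICLE_SCORE = (4.00, 0.22)
EAE_REGIMENS = [
    # (animal_dose mg/kg, frequency/day, score mean, score sd, significant)
    (25.0, 3, 3.70, 0.15, False),
    (30.0, 1, 3.38, 0.27, False),
    (100.0, 3, 2.36, 0.27, True),
    (150.0, 2, 2.55, 0.27, True),
    (300.0, 1, 2.78, 0.25, True),
]
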