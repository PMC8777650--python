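"""Delimited-text I/O for the profile types.

Formats (all comma-separated, ``#`` comment lines allowed):

* plasma profiles:      ``time_h,conc_ug_ml``
* dissolution profiles: ``time_h,f_diss`` (fraction) or
                        ``time_h,pct_dissolved`` (percent, auto-detected)
* absorption profiles:  ``time_h,f_abs``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dissolution import DissolutionProfile
from .ivivc import AbsorptionProfile
from .pk import ConcTimeSeries

__all__ = [
    "read_conc_time",
    "write_conc_time",
    "read_dissolution",
    "write_dissolution",
    "read_absorption",
    "write_absorption",
]


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_conc_time(path, dose: float = 0.0, label: str = "") -> ConcTimeSeries:
    df = _read(path)
    return ConcTimeSeries(
        times=df["time_h"].to_numpy(float),
        concentrations=df["conc_ug_ml"].to_numpy(float),
        dose=dose,
        label=label or Path(path).stem,
    )


def write_conc_time(profile: ConcTimeSeries, path) -> None:
    pd.DataFrame(
        {"time_h": profile.times, "conc_ug_ml": profile.concentrations}
    ).to_csv(path, index=False)


def read_dissolution(path, label: str = "") -> DissolutionProfile:
    df = _read(path)
    if "f_diss" in df.columns:
        f = df["f_diss"].to_numpy(float)
    elif "pct_dissolved" in df.columns:
        f = df["pct_dissolved"].to_numpy(float) / 100.0
    else:
        raise ValueError("expected a 'f_diss' or 'pct_dissolved' column")
    return DissolutionProfile(
        times=df["time_h"].to_numpy(float), f_diss=f, label=label or Path(path).stem
    )


def write_dissolution(profile: DissolutionProfile, path, percent: bool = False) -> None:
    if percent:
        df = pd.DataFrame(
            {"time_h": profile.times, "pct_dissolved": 100.0 * profile.f_diss}
        )
    else:
        df = pd.DataFrame({"time_h": profile.times, "f_diss": profile.f_diss})
    df.to_csv(path, index=False)


def read_absorption(path, dose: float = 0.0) -> AbsorptionProfile:
    df = _read(path)
    f_abs = df["f_abs"].to_numpy(float)
    delta = np.diff(np.concatenate([[0.0], f_abs]))
    return AbsorptionProfile(
        times=df["time_h"].to_numpy(float),
        f_abs=f_abs,
        delta_f_abs=delta,
        dose=dose,
    )


def write_absorption(profile: AbsorptionProfile, path) -> None:
    pd.DataFrame({"time_h": profile.times, "f_abs": profile.f_abs}).to_csv(
        path, index=False
    )
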