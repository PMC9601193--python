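"""Transwell transport arithmetic: apparent permeability and efflux ratios.

For a compound dosed at concentration C0 into the donor chamber of a
transwell insert, the apparent permeability is

    Papp = (dQ/dt) * Vr / (C0 * A)        [cm/s]

with dQ/dt the slope of receiver concentration vs time (µM/s) over the
linear (sink-condition) portion of the curve, Vr the receiver volume (mL),
and A the insert area (cm²). The efflux ratio Papp(B→A)/Papp(A→B) > 1
indicates active apical efflux; its reduction under an inhibitor is the
functional confirmation arm of the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransportSeries",
    "papp",
    "efflux_ratio",
    "efflux_inhibition",
    "DEFAULT_AREA_CM2",
    "DEFAULT_APICAL_VOLUME_ML",
    "DEFAULT_BASOLATERAL_VOLUME_ML",
]

# 96-well transwell geometry defaults.
DEFAULT_AREA_CM2 = 0.11
DEFAULT_APICAL_VOLUME_ML = 0.1
DEFAULT_BASOLATERAL_VOLUME_ML = 0.3

#: Receiver concentration below this fraction of C0 counts as sink condition.
SINK_FRACTION = 0.10


@dataclass(frozen=True)
class TransportSeries:
    """Receiver-compartment concentration vs time for one transwell run.

    direction is "AtoB" (apical→basolateral) or "BtoA"; times in seconds,
    concentrations in µM; c0 the initial donor concentration (µM); vr the
    receiver volume (mL); area the insert area (cm²).
    """

    direction: str
    times: np.ndarray
    receiver_concentration: np.ndarray
    c0: float
    vr: float
    area: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self,
            "receiver_concentration",
            np.asarray(self.receiver_concentration, dtype=float),
        )
        if self.direction not in ("AtoB", "BtoA"):
            raise ValueError(f"direction must be AtoB or BtoA, got {self.direction!r}")
        if self.times.shape != self.receiver_concentration.shape:
            raise ValueError("times and receiver_concentration differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("c0", "vr", "area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def papp(series: TransportSeries, slope_tolerance: float = 1e-12) -> float:
    """Apparent permeability (cm/s) from a receiver concentration series.

    The slope is the least-squares fit of receiver concentration vs time
    over the linear window — all points with receiver < 10% of C0 — falling
    back to all points when fewer than three qualify. A fitted slope more
    negative than ``-slope_tolerance * c0`` triggers a warning and returns
    0 (no measurable flux).
    """
    t, r = series.times, series.receiver_concentration
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(r < 0):
        raise ValueError("receiver concentrations must be non-negative")
    mask = r < SINK_FRACTION * series.c0
    if mask.sum() >= 3:
        t, r = t[mask], r[mask]
    if np.ptp(t) == 0:
        raise ValueError("degenerate linear window: no time spread")
    slope = float(np.polyfit(t, r, 1)[0])  # µM / s
    if slope <= slope_tolerance * series.c0:
        if slope < -slope_tolerance * series.c0:
            warnings.warn(
                f"negative receiver slope ({slope:.3g} µM/s); reporting Papp = 0",
                stacklevel=2,
            )
        return 0.0
    # µM/s * mL / (µM * cm²) = cm³/(s·cm²) = cm/s
    return slope * series.vr / (series.c0 * series.area)


def efflux_ratio(papp_ab: float, papp_ba: float) -> float:
    """Efflux ratio Papp(B→A) / Papp(A→B); undefined when papp_ab is 0."""
    if papp_ab <= 0:
        raise ValueError("efflux ratio undefined: Papp(A to B) must be > 0")
    return papp_ba / papp_ab


def efflux_inhibition(er_control: float, er_inhibited: float) -> float:
    """Percent reduction of the efflux ratio under an inhibitor.

    100 × (ER_control − ER_inhibited)/ER_control; negative when the ratio
    increased (returned as-is, signed).
    """
    if er_control <= 0:
        raise ValueError("control efflux ratio must be > 0")
    return 100.0 * (er_control - er_inhibited) / er_control
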