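"""Pump and system characteristic framework for sponge pumping units.

A basic pumping unit (one ostium-of-zero-length plus its neighboring
choanocytes) is characterized by its maximum pumping rate Q_max at zero
pressure load and maximum pressure P_max at zero net flow.  Because the
governing equations are linear at low Reynolds number, the characteristic
is the straight line

    P_hat = 1 - Q_hat,      P_hat = P/P_max,  Q_hat = Q/Q_max.

The canal system (here, the ostium tube treated as a Poiseuille resistance
R_ost = 128 mu L / (pi D^4)) imposes the system curve

    P_hat = (R_ost / C_pump) * Q_hat,     C_pump = P_max / Q_max,

and the intersection of the two lines is the operating point:
Q_hat_op = 1/(1 + R_hat), P_hat_op = R_hat/(1 + R_hat), with
R_hat = R_ost/C_pump.  Syconoid units run near R_hat ~ 1 (half capacity);
gasket-bearing leucon units near R_hat ~ 0.1 (almost full capacity); a
gasket-less unit on a narrow leucon canal system (R_hat ~ 100) would be
effectively stalled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import InvalidGeometryError, WATER_VISCOSITY


@dataclass(frozen=True)
class PumpCharacteristic:
    """Linear pump characteristic of a basic pumping unit."""

    Q_max: float            # um^3/s at zero pressure load
    P_max: float            # Pa at zero net flow
    r_squared: float = 1.0  # linear-fit quality of the samples

    def __post_init__(self) -> None:
        if self.Q_max <= 0 or self.P_max <= 0:
            raise ValueError("Q_max and P_max must be > 0")

    @property
    def C_pump(self) -> float:
        """Characteristic resistance P_max/Q_max, Pa s / um^3."""
        return self.P_max / self.Q_max

    @property
    def C_pump_micro(self) -> float:
        """C_pump in uPa s um^-3 (the conventionally reported unit)."""
        return self.C_pump * 1e6

    @property
    def C_pump_micro_rounded(self) -> float:
        """C_pump in uPa s um^-3, rounded to the nearest ten."""
        return round(self.C_pump_micro / 10.0) * 10.0


@dataclass(frozen=True)
class SystemCurve:
    """Pressure-flow relation of the canal resistance."""

    R_ost: float  # Pa s / um^3

    def __post_init__(self) -> None:
        if self.R_ost < 0:
            raise ValueError("canal resistance must be >= 0")


@dataclass(frozen=True)
class OperatingPoint:
    """Intersection of pump and system characteristics (dimensionless)."""

    Q_hat: float
    P_hat: float
    R_hat: float


def poiseuille_resistance(
    D: float, L: float, mu: float = WATER_VISCOSITY
) -> float:
    """Poiseuille resistance 128 mu L / (pi D^4) of a circular canal.

    D, L in um, mu in Pa s; result in Pa s / um^3.
    """
    if D <= 0:
        raise InvalidGeometryError("canal diameter must be > 0")
    if L < 0:
        raise InvalidGeometryError("canal length must be >= 0")
    return 128.0 * mu * L / (np.pi * D**4)


def operating_point(pump: PumpCharacteristic, system: SystemCurve) -> OperatingPoint:
    """Operating condition where the pump and system lines intersect."""
    r_hat = system.R_ost / pump.C_pump
    q = 1.0 / (1.0 + r_hat)
    return OperatingPoint(Q_hat=q, P_hat=r_hat * q, R_hat=r_hat)


def characterize_pump(
    samples, min_r_squared: float = 0.999
) -> PumpCharacteristic:
    """Fit the linear characteristic to simulated (back-pressure, flow) pairs.

    ``samples`` is a sequence of (dP, Q) with dP the imposed adverse load
    (Pa) and Q the period-averaged pumping rate (um^3/s).  Least-squares
    line through the points; Q_max is the zero-pressure intercept and P_max
    the zero-flow intercept.  Raises on degenerate sample sets or when the
    fit quality falls below ``min_r_squared`` (the characteristic of a
    Stokes-regime pump must be linear).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need at least two (dP, Q) samples")
    dp, q = arr[:, 0], arr[:, 1]
    if np.ptp(q) == 0 or np.ptp(dp) == 0:
        raise ValueError("degenerate samples: no spread in pressure or flow")
    # fit P = a + b Q ;  expect b < 0
    b, a = np.polyfit(q, dp, 1)
    if b >= 0 or a <= 0:
        raise ValueError("samples do not describe a pump (non-negative slope)")
    pred = a + b * q
    sstot = float(np.sum((dp - dp.mean()) ** 2))
    ssres = float(np.sum((dp - pred) ** 2))
    r2 = 1.0 - ssres / sstot if sstot > 0 else 1.0
    if len(arr) > 2 and r2 < min_r_squared:
        raise ValueError(f"pump characteristic not linear: R^2 = {r2:.5f}")
    p_max = float(a)
    q_max = float(-a / b)
    return PumpCharacteristic(Q_max=q_max, P_max=p_max, r_squared=float(r2))


def characteristic_plot_data(r_hats=(0.1, 1.0, 100.0), n: int = 101) -> dict:
    """Dimensionless pump/system lines with marked operating points."""
    q = np.linspace(0.0, 1.0, n)
    data = {
        "Q_hat": q,
        "pump_P_hat": 1.0 - q,
        "system": {},
        "operating_points": {},
    }
    for r in r_hats:
        data["system"][r] = r * q
        qop = 1.0 / (1.0 + r)
        data["operating_points"][r] = (qop, r * qop)
    return data
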