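"""Experimental computations: dye-speed flux, bead-calibrated cytometry, and
In-Ex retention efficiency.

The In-Ex method compares prey concentrations in water inhaled (Cin) and
exhaled (Cex) by a suspension feeder; retention efficiency per prey class
is 100 (Cin - Cex)/Cin.  Cytometry concentrations are calibrated by spiking
every sample with beads of known stock concentration: the analyzed volume
is the bead count divided by the stock concentration.  The excurrent flux
is the dye-front jet speed times the osculum area (plug-flow assumption).

Tables are pandas DataFrames.  The In-Ex table has one row per sample:
columns ``sponge``, ``pair``, ``flow`` ("in"/"ex"), one count column per
prey class (default classes Euk, HNA, LNA), ``beads`` and
``bead_stock`` (beads/uL).  The flux table has one row per dye replicate:
``sponge``, ``replicate``, ``distance_mm``, ``time_s``, ``osculum_area_mm2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PREY_CLASSES = ("Euk", "HNA", "LNA")

#: published per-choanocyte pumping-rate range for leucon sponges, um^3/s
LEUCON_QCH_RANGE = (17.0, 236.0)


class MeasurementError(ValueError):
    """Raised for non-physical measurement values."""


# ---------------------------------------------------------------------------
# dye-speed flux


@dataclass(frozen=True)
class ExcurrentFlow:
    jet_speed_mm_s: float
    osculum_area_mm2: float
    flow_mm3_s: float

    @property
    def flow_um3_s(self) -> float:
        return self.flow_mm3_s * 1e9


def excurrent_flow(measurements: pd.DataFrame) -> ExcurrentFlow:
    """Excurrent volume flow from dye-front replicates of one sponge.

    Jet speed is the replicate-mean of distance/time; the flow is speed
    times osculum area under a plug-flow profile.
    """
    if len(measurements) < 1:
        raise MeasurementError("need at least one dye replicate")
    t = measurements["time_s"].to_numpy(dtype=float)
    d = measurements["distance_mm"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise MeasurementError("dye transit times must be > 0")
    if np.any(d <= 0):
        raise MeasurementError("dye distances must be > 0")
    area = float(measurements["osculum_area_mm2"].iloc[0])
    if area < 0:
        raise MeasurementError("osculum area must be >= 0")
    speed = float(np.mean(d / t))
    return ExcurrentFlow(
        jet_speed_mm_s=speed,
        osculum_area_mm2=area,
        flow_mm3_s=speed * area,
    )


@dataclass(frozen=True)
class PerUnitRates:
    Q_ost: float       # um^3/s per ostium
    Q_ch: float        # um^3/s per choanocyte
    in_leucon_range: bool


def per_unit_rates(
    total_flux_um3_s: float, n_ostia: int, choanocytes_per_ostium: int = 24
) -> PerUnitRates:
    """Per-ostium and per-choanocyte pumping rates from the whole-sponge flux."""
    if n_ostia <= 0 or choanocytes_per_ostium <= 0:
        raise MeasurementError("ostium and choanocyte counts must be > 0")
    q_ost = total_flux_um3_s / n_ostia
    q_ch = q_ost / choanocytes_per_ostium
    lo, hi = LEUCON_QCH_RANGE
    return PerUnitRates(
        Q_ost=q_ost, Q_ch=q_ch, in_leucon_range=bool(lo <= q_ch <= hi)
    )


# ---------------------------------------------------------------------------
# cytometry


def bead_calibrated_concentration(
    class_counts, bead_count: float, bead_stock: float
) -> dict[str, float]:
    """Concentrations (cells/uL) from event counts and the bead spike.

    Analyzed volume = bead_count / bead_stock (uL); concentration of each
    prey class = events / analyzed volume.
    """
    if bead_count <= 0:
        raise MeasurementError("bead count must be > 0 for calibration")
    if bead_stock <= 0:
        raise MeasurementError("bead stock concentration must be > 0")
    volume = bead_count / bead_stock
    return {k: float(v) / volume for k, v in dict(class_counts).items()}


def retention_efficiency(c_in: float, c_ex: float) -> float:
    """Retention efficiency 100 (Cin - Cex)/Cin in percent.

    Negative values (exhaled exceeding inhaled) are preserved as-is so that
    summary statistics remain unbiased.
    """
    if c_in <= 0:
        raise MeasurementError("inhaled concentration must be > 0")
    return 100.0 * (c_in - c_ex) / c_in


def pair_retention(
    table: pd.DataFrame, classes=PREY_CLASSES
) -> pd.DataFrame:
    """Per-pair retention efficiencies from an In-Ex sample table.

    Returns one row per (sponge, pair) with a retention column per class.
    """
    required = {"sponge", "pair", "flow", "beads", "bead_stock", *classes}
    missing = required - set(table.columns)
    if missing:
        raise MeasurementError(f"In-Ex table is missing columns: {sorted(missing)}")
    rows = []
    for (sponge, pair), grp in table.groupby(["sponge", "pair"]):
        flows = set(grp["flow"])
        if flows != {"in", "ex"}:
            raise MeasurementError(
                f"pair ({sponge}, {pair}) must have exactly one 'in' and one 'ex' sample"
            )
        conc = {}
        for _, row in grp.iterrows():
            conc[row["flow"]] = bead_calibrated_concentration(
                {c: row[c] for c in classes}, row["beads"], row["bead_stock"]
            )
        rec = {"sponge": sponge, "pair": pair}
        for c in classes:
            rec[c] = retention_efficiency(conc["in"][c], conc["ex"][c])
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# box summaries


@dataclass(frozen=True)
class BoxStats:
    """Box-plot statistics with whiskers by the 1.5 x IQR rule."""

    median: float
    q1: float
    q3: float
    whisker_lo: float     # most extreme data point within 1.5 IQR of Q1
    whisker_hi: float
    outliers: tuple[float, ...]
    mean: float
    sd: float
    se: float
    n: int


@dataclass(frozen=True)
class RetentionResult:
    per_class: dict[str, BoxStats] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: vars(v) | {"outliers": list(v.outliers)} for k, v in self.per_class.items()}
        ).T


def box_stats(values) -> BoxStats:
    """Order statistics of one sample; quartiles use linear interpolation
    between order statistics (the common 'type 7' convention)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise MeasurementError("need at least three values for a box summary")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(sorted(x[(x < lo_fence) | (x > hi_fence)]))
    sd = float(np.std(x, ddof=1))
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=outliers,
        mean=float(np.mean(x)),
        sd=sd,
        se=sd / np.sqrt(len(x)),
        n=len(x),
    )


def retention_summary(retentions: pd.DataFrame, classes=PREY_CLASSES) -> RetentionResult:
    """Per-class box summaries of per-pair retention efficiencies.

    Both the standard error and the standard deviation accompany the mean
    so either convention of a "mean +/- x %" headline can be compared.
    """
    res = RetentionResult()
    for c in classes:
        res.per_class[c] = box_stats(retentions[c].to_numpy())
    return res
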