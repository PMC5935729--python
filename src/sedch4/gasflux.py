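"""Headspace gas accounting for sealed sediment incubations.

Sealed jars accumulate CH4 and CO2 in their headspace between periodic
gas-chromatograph samplings.  Each sampling event injects N2 to maintain
pressure, homogenizes, and withdraws an aliquot, so the recorded
concentration reflects a diluted, post-injection mixing state and part of
the produced gas leaves the jar at every event.  This module inverts that
event bookkeeping: it reconstructs cumulative production per jar by adding
back every withdrawn portion, and normalizes totals per unit sediment area.

All gas amounts use the ideal-gas law at the incubation temperature and
pressure; no dissolved-phase partitioning is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_MASS_G_MOL",
    "JarSpec",
    "HeadspaceSeries",
    "ProductionEstimate",
    "ppm_to_mass",
    "mass_to_ppm",
    "cumulative_production",
    "summarize_treatments",
    "read_headspace_csv",
]

#: Molar masses (g/mol) of the gases the incubation assay quantifies.
MOLAR_MASS_G_MOL = {"CH4": 16.04, "CO2": 44.01}

_R = 8.314462618  # J / (mol K)


@dataclass(frozen=True)
class JarSpec:
    """Physical description of one incubation jar.

    The default headspace volume corresponds to a 250 mL jar holding a
    4.5 cm deep sediment plug of 28.3 cm^2 cross-section (~123 mL of
    headspace).  Injection and withdrawal volumes describe one sampling
    event: N2 in, homogenize, aliquot out.
    """

    headspace_volume_mL: float = 250.0 - 4.5 * 28.3
    sediment_area_cm2: float = 28.3
    temperature_C: float = 20.5
    pressure_kPa: float = 101.325
    inject_mL: float = 10.0
    withdraw_mL: float = 10.0

    def __post_init__(self) -> None:
        if self.headspace_volume_mL <= 0 or self.sediment_area_cm2 <= 0:
            raise ValueError("jar volumes and areas must be positive")
        if self.inject_mL < 0 or self.withdraw_mL < 0:
            raise ValueError("event volumes must be nonnegative")
        if self.withdraw_mL > self.headspace_volume_mL + self.inject_mL:
            raise ValueError("cannot withdraw more than the mixed headspace")

    @property
    def sediment_area_m2(self) -> float:
        return self.sediment_area_cm2 * 1e-4


@dataclass
class HeadspaceSeries:
    """Ordered headspace concentration measurements for one jar and gas.

    Concentrations are ppm by volume recorded in the post-injection mixed
    state (the sampling protocol homogenizes the N2 injection before the
    aliquot is drawn).
    """

    jar_id: str
    treatment: str
    om_frac: float
    spike: bool
    gas: str
    days: np.ndarray
    ppm: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.gas not in MOLAR_MASS_G_MOL:
            raise ValueError(f"unknown gas {self.gas!r}")
        if self.days.shape != self.ppm.shape or self.days.ndim != 1:
            raise ValueError("days and ppm must be 1-D arrays of equal length")
        if len(self.days) and np.any(np.diff(self.days) <= 0):
            raise ValueError("sampling days must be strictly increasing")
        if np.any(self.ppm < 0):
            raise ValueError("concentrations must be nonnegative")


@dataclass
class ProductionEstimate:
    """Cumulative production reconstructed from one headspace series.

    ``total_mg`` always equals ``final_remaining_mg`` plus the sum of the
    per-event ``removed_mg`` ledger; ``rate_mg_m2`` divides by sediment area.
    Events whose implied interval production is negative (a concentration
    drop larger than the removals explain) are flagged, never clamped.
    """

    jar_id: str
    treatment: str
    om_frac: float
    spike: bool
    gas: str
    total_mg: float
    rate_mg_m2: float
    removed_mg: np.ndarray
    final_remaining_mg: float
    interval_production_mg: np.ndarray
    negative_intervals: list[int] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.negative_intervals


def ppm_to_mass(
    ppm: float | np.ndarray,
    volume_mL: float,
    temperature_C: float,
    pressure_kPa: float,
    gas: str,
) -> float | np.ndarray:
    """Convert a mixing ratio (ppmv) in a known volume to mass in mg.

    Uses the ideal gas law: n_total = P V / (R T); the gas of interest
    contributes ``ppm * 1e-6`` of those moles.
    """
    if gas not in MOLAR_MASS_G_MOL:
        raise ValueError(f"unknown gas {gas!r}; expected one of {sorted(MOLAR_MASS_G_MOL)}")
    ppm = np.asarray(ppm, dtype=float)
    if np.any(ppm < 0) or volume_mL < 0:
        raise ValueError("ppm and volume must be nonnegative")
    n_total_mol = (pressure_kPa * 1e3) * (volume_mL * 1e-6) / (_R * (temperature_C + 273.15))
    mass_mg = n_total_mol * ppm * 1e-6 * MOLAR_MASS_G_MOL[gas] * 1e3
    return float(mass_mg) if mass_mg.ndim == 0 else mass_mg


def mass_to_ppm(
    mass_mg: float | np.ndarray,
    volume_mL: float,
    temperature_C: float,
    pressure_kPa: float,
    gas: str,
) -> float | np.ndarray:
    """Inverse of :func:`ppm_to_mass` (used by the forward simulator)."""
    if gas not in MOLAR_MASS_G_MOL:
        raise ValueError(f"unknown gas {gas!r}")
    mass_mg = np.asarray(mass_mg, dtype=float)
    n_total_mol = (pressure_kPa * 1e3) * (volume_mL * 1e-6) / (_R * (temperature_C + 273.15))
    ppm = mass_mg / (n_total_mol * MOLAR_MASS_G_MOL[gas] * 1e3) * 1e6
    return float(ppm) if ppm.ndim == 0 else ppm


def cumulative_production(
    series: HeadspaceSeries,
    jar: JarSpec | None = None,
    measure_state: str = "mixed",
) -> ProductionEstimate:
    """Reconstruct total gas production from periodic mixed-state readings.

    Event model for measurement k: the headspace (volume V_k) holds mass
    m_k; injecting ``inject_mL`` of N2 dilutes it to the mixed concentration
    that the chromatograph records; withdrawing ``withdraw_mL`` removes
    ``m_k * withdraw / (V_k + inject)``.  Total production is the final
    remaining mass plus everything removed along the way, i.e. the protocol
    of adding back withdrawn portions at day 150.

    Parameters
    ----------
    measure_state:
        ``"mixed"`` (default) interprets readings as post-injection;
        ``"pre"`` interprets them as taken before the N2 injection.
    """
    jar = jar or JarSpec()
    if measure_state not in ("mixed", "pre"):
        raise ValueError("measure_state must be 'mixed' or 'pre'")
    if len(series.days) == 0:
        raise ValueError("series must contain at least one measurement")

    volume = jar.headspace_volume_mL
    remaining = 0.0
    removed: list[float] = []
    intervals: list[float] = []
    negative: list[int] = []
    for k in range(len(series.days)):
        mixed_volume = volume + jar.inject_mL
        meas_volume = mixed_volume if measure_state == "mixed" else volume
        mass = ppm_to_mass(
            series.ppm[k], meas_volume, jar.temperature_C, jar.pressure_kPa, series.gas
        )
        produced = mass - remaining
        if produced < 0:
            negative.append(k)
        intervals.append(produced)
        r = mass * jar.withdraw_mL / mixed_volume
        removed.append(r)
        remaining = mass - r
        volume = volume + jar.inject_mL - jar.withdraw_mL

    total = remaining + float(np.sum(removed))
    return ProductionEstimate(
        jar_id=series.jar_id,
        treatment=series.treatment,
        om_frac=series.om_frac,
        spike=series.spike,
        gas=series.gas,
        total_mg=total,
        rate_mg_m2=total / jar.sediment_area_m2,
        removed_mg=np.asarray(removed),
        final_remaining_mg=remaining,
        interval_production_mg=np.asarray(intervals),
        negative_intervals=negative,
    )


def summarize_treatments(
    estimates: list[ProductionEstimate] | pd.DataFrame,
    strict: bool = False,
) -> pd.DataFrame:
    """Per (treatment, OM, spike, gas) group: n, mean and SE of area rates.

    With ``strict=True``, jars flagged for negative implied production are
    excluded from the summary (they are always retained otherwise).
    """
    if isinstance(estimates, pd.DataFrame):
        df = estimates.copy()
        if "consistent" not in df.columns:
            df["consistent"] = True
    else:
        df = pd.DataFrame(
            {
                "jar_id": [e.jar_id for e in estimates],
                "treatment": [e.treatment for e in estimates],
                "om_frac": [e.om_frac for e in estimates],
                "spike": [e.spike for e in estimates],
                "gas": [e.gas for e in estimates],
                "rate_mg_m2": [e.rate_mg_m2 for e in estimates],
                "consistent": [e.consistent for e in estimates],
            }
        )
    if strict:
        df = df[df["consistent"]]
    grouped = df.groupby(["treatment", "om_frac", "spike", "gas"], sort=True)["rate_mg_m2"]
    out = grouped.agg(n="count", mean_rate_mg_m2="mean", se_rate_mg_m2="sem").reset_index()
    out["se_rate_mg_m2"] = out["se_rate_mg_m2"].fillna(0.0)
    return out


def read_headspace_csv(path) -> list[HeadspaceSeries]:
    """Load the long-format headspace table into per-(jar, gas) series.

    Expected columns: jar_id, treatment, om_pct, spike, day, gas, ppm.
    """
    df = pd.read_csv(path)
    series = []
    for (jar_id, gas), g in df.groupby(["jar_id", "gas"], sort=True):
        g = g.sort_values("day")
        series.append(
            HeadspaceSeries(
                jar_id=str(jar_id),
                treatment=str(g["treatment"].iloc[0]),
                om_frac=float(g["om_pct"].iloc[0]) / 100.0,
                spike=bool(g["spike"].iloc[0]),
                gas=str(gas),
                days=g["day"].to_numpy(float),
                ppm=g["ppm"].to_numpy(float),
            )
        )
    return series
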