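"""Ecosystem-scale CH4 projection for Boreal Shield lakes.

Per-lake seasonal CH4 production is the product of an incubation-derived
areal production rate and the lake area expected to be covered by emergent
macrophytes: occurrence probability x habitat fraction x surface area.
Totals are scaled from the surficial sediment layer to the full profile,
expressed in CO2 equivalents, and compared between the current climate and
an ensemble of future (GCM, RCP) occurrence scenarios with Monte-Carlo
propagation of rate and scenario uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UpscaleParams",
    "UpscaleModel",
    "UpscaleResults",
    "lake_production",
    "to_co2eq",
    "scenario_columns",
]

AREA_RANGE_KM2 = (0.1, 1000.0)


@dataclass(frozen=True)
class UpscaleParams:
    """Knobs of the upscaling model.

    habitat_fraction:
        Maximum fraction of lake area coverable by emergent macrophytes
        (0.28 for boreal lakes in the 0.1-1000 km^2 range); an occurrence
        probability of 1 colonizes exactly this fraction.
    rate_mean_mg_m2, rate_se_mg_m2:
        Areal CH4 production over a 150-day season (macrophyte-litter
        sediment default 7.22e3 mg m^-2) and its standard error, sampled as
        a zero-truncated normal in the Monte Carlo.
    surficial_fraction:
        Share of whole-profile production attributed to the incubated
        surficial layer (0.70); totals divide by it to scale up.
    gwp_co2eq:
        kg CO2 equivalent per kg CH4 (25).
    colonization_mode:
        "expected" counts colonized lakes as the sum of occurrence
        probabilities; "threshold" counts lakes with p >= colonization_p.
    """

    habitat_fraction: float = 0.28
    rate_mean_mg_m2: float = 7.22e3
    rate_se_mg_m2: float = 7.22e2
    surficial_fraction: float = 0.70
    gwp_co2eq: float = 25.0
    colonization_mode: str = "expected"
    colonization_p: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.habitat_fraction <= 1 and 0 < self.surficial_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.gwp_co2eq <= 0:
            raise ValueError("gwp must be positive")
        if self.colonization_mode not in ("expected", "threshold"):
            raise ValueError("colonization_mode must be 'expected' or 'threshold'")


def lake_production(
    area_km2,
    p_occ,
    params: UpscaleParams,
    rate_mg_m2: float | None = None,
):
    """Seasonal CH4 production (kg) for lakes with given occurrence probability.

    coverage_m2 = p_occ * habitat_fraction * area_km2 * 1e6
    production_kg = rate * coverage_m2 * 1e-6 / surficial_fraction
    """
    area_km2 = np.asarray(area_km2, dtype=float)
    p_occ = np.asarray(p_occ, dtype=float)
    if np.any(p_occ < 0) or np.any(p_occ > 1):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    if np.any(area_km2 < 0):
        raise ValueError("areas must be nonnegative")
    rate = params.rate_mean_mg_m2 if rate_mg_m2 is None else rate_mg_m2
    coverage_m2 = p_occ * params.habitat_fraction * area_km2 * 1e6
    out = rate * coverage_m2 * 1e-6 / params.surficial_fraction
    return float(out) if out.ndim == 0 else out


def to_co2eq(ch4_kg, gwp: float = 25.0):
    """Convert a CH4 mass to CO2 equivalents (kg CH4 x GWP)."""
    if gwp <= 0:
        raise ValueError("gwp must be positive")
    out = np.asarray(ch4_kg, dtype=float) * gwp
    return float(out) if out.ndim == 0 else out


def scenario_columns(table: pd.DataFrame) -> list[str]:
    """Future occurrence-probability columns of a lake table (p_<GCM>_rcp<RCP>)."""
    return [c for c in table.columns if c.startswith("p_") and c != "p_current"]


class UpscaleModel:
    """Current-vs-future CH4 totals over a lake table with MC uncertainty.

    Parameters
    ----------
    table:
        Lake table with ``lake_id``, ``area_km2``, ``p_current`` and one
        probability column per future (GCM, RCP) scenario.
    params:
        :class:`UpscaleParams`; defaults describe the macrophyte-litter
        production rate and the standard habitat/profile/GWP constants.
    """

    def __init__(self, table: pd.DataFrame, params: UpscaleParams | None = None):
        self.params = params or UpscaleParams()
        required = {"lake_id", "area_km2", "p_current"}
        if not required.issubset(table.columns):
            raise ValueError(f"lake table must contain {sorted(required)}")
        lo, hi = AREA_RANGE_KM2
        a = table["area_km2"].to_numpy(float)
        if np.any(a < lo) or np.any(a > hi):
            raise ValueError(f"lake areas must lie within {lo}-{hi} km^2")
        self.scenarios = scenario_columns(table)
        if not self.scenarios:
            raise ValueError("need at least one future scenario column")
        probs = table[["p_current", *self.scenarios]].to_numpy(float)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("occurrence probabilities must lie in [0, 1]")
        self.table = table.reset_index(drop=True)

    def per_lake(self, rate_mg_m2: float | None = None) -> pd.DataFrame:
        """Deterministic per-lake CH4 (kg) and CO2-eq, current and per scenario."""
        p = self.params
        out = self.table[["lake_id", "area_km2"]].copy()
        cur = lake_production(
            self.table["area_km2"], self.table["p_current"], p, rate_mg_m2
        )
        out["ch4_kg_current"] = cur
        out["co2eq_kg_current"] = to_co2eq(cur, p.gwp_co2eq)
        for col in self.scenarios:
            fut = lake_production(self.table["area_km2"], self.table[col], p, rate_mg_m2)
            out[f"ch4_kg_{col[2:]}"] = fut
            out[f"co2eq_kg_{col[2:]}"] = to_co2eq(fut, p.gwp_co2eq)
        return out

    def colonized_counts(self) -> pd.DataFrame:
        """Colonized-lake counts, current and per scenario, under the mode."""
        p = self.params
        def count(col):
            probs = self.table[col].to_numpy(float)
            if p.colonization_mode == "expected":
                return float(probs.sum())
            return float((probs >= p.colonization_p).sum())
        rows = [{"scenario": "current", "colonized_lakes": count("p_current")}]
        rows += [
            {"scenario": c[2:], "colonized_lakes": count(c)} for c in self.scenarios
        ]
        return pd.DataFrame(rows)

    def simulate(self, n_mc: int = 1000, seed: int | None = None) -> "UpscaleResults":
        """Monte-Carlo ensemble of current and future totals.

        Each draw samples one production rate from a zero-truncated
        Normal(mean, SE) and one future scenario column uniformly from the
        GCM x RCP ensemble, then computes current and future totals with the
        same rate (so the percent change is rate-free) and the percent
        change.  Medians and 2.5/97.5% quantiles summarize the draws.
        """
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        rng = np.random.default_rng(seed)
        p = self.params
        area = self.table["area_km2"].to_numpy(float)
        p_cur = self.table["p_current"].to_numpy(float)
        fut_probs = self.table[self.scenarios].to_numpy(float)

        # rate-free geometry: production = rate * (coverage sum) / surficial
        base_cur = float(np.sum(p_cur * p.habitat_fraction * area))  # km^2-weighted
        base_fut = fut_probs.T * p.habitat_fraction * area  # (n_scen, n_lakes)
        base_fut_tot = base_fut.sum(axis=1)

        rates = rng.normal(p.rate_mean_mg_m2, p.rate_se_mg_m2, size=n_mc)
        while np.any(rates < 0):  # zero-truncation by redraw
            bad = rates < 0
            rates[bad] = rng.normal(p.rate_mean_mg_m2, p.rate_se_mg_m2, size=bad.sum())
        scen_idx = rng.integers(0, len(self.scenarios), size=n_mc)

        unit = 1e6 * 1e-6 / p.surficial_fraction  # km^2*mg/m^2 -> kg
        cur_draws = rates * base_cur * unit
        fut_draws = rates * base_fut_tot[scen_idx] * unit
        with np.errstate(divide="ignore", invalid="ignore"):
            change = np.where(
                cur_draws > 0, (fut_draws / cur_draws - 1.0) * 100.0, np.nan
            )
        undefined = bool(np.any((cur_draws == 0) & (fut_draws > 0)))

        per_scenario = pd.DataFrame(
            {
                "scenario": [c[2:] for c in self.scenarios],
                "ch4_kg_total": p.rate_mean_mg_m2 * base_fut_tot * unit,
                "pct_change_vs_current": (base_fut_tot / base_cur - 1.0) * 100.0
                if base_cur > 0
                else np.nan,
            }
        )
        q = lambda a: np.nanquantile(a, [0.025, 0.5, 0.975])
        return UpscaleResults(
            params=p,
            n_mc=n_mc,
            current_total_ch4_kg=p.rate_mean_mg_m2 * base_cur * unit,
            future_total_ch4_kg_quantiles=q(fut_draws),
            pct_change_quantiles=q(change),
            pct_change_draws=change,
            future_draws_ch4_kg=fut_draws,
            current_draws_ch4_kg=cur_draws,
            per_scenario=per_scenario,
            colonized=self.colonized_counts(),
            undefined_change=undefined,
        )


@dataclass
class UpscaleResults:
    """Monte-Carlo summary of the current-to-future CH4 change.

    ``undefined_change`` marks draws where a zero current total met a
    nonzero future total (percent change undefined, reported as NaN, never
    infinity).  CO2-equivalent figures are CH4 x GWP throughout.
    """

    params: UpscaleParams
    n_mc: int
    current_total_ch4_kg: float
    future_total_ch4_kg_quantiles: np.ndarray
    pct_change_quantiles: np.ndarray
    pct_change_draws: np.ndarray
    future_draws_ch4_kg: np.ndarray
    current_draws_ch4_kg: np.ndarray
    per_scenario: pd.DataFrame
    colonized: pd.DataFrame
    undefined_change: bool

    @property
    def current_total_co2eq_kg(self) -> float:
        return to_co2eq(self.current_total_ch4_kg, self.params.gwp_co2eq)

    @property
    def min_ensemble_pct_change(self) -> float:
        """Smallest per-scenario change — the conservative ensemble bound."""
        return float(self.per_scenario["pct_change_vs_current"].min())

    def summary(self) -> str:
        f_lo, f_md, f_hi = self.future_total_ch4_kg_quantiles
        c_lo, c_md, c_hi = self.pct_change_quantiles
        lines = [
            "Boreal-Shield CH4 upscaling (Monte Carlo, "
            f"{self.n_mc} draws, {len(self.per_scenario)} scenarios)",
            f"  current total:  {self.current_total_ch4_kg:,.0f} kg CH4 "
            f"({self.current_total_co2eq_kg:,.0f} kg CO2-eq)",
            f"  future total:   {f_md:,.0f} kg CH4 [{f_lo:,.0f}, {f_hi:,.0f}]",
            f"  percent change: {c_md:+.1f}% [{c_lo:+.1f}%, {c_hi:+.1f}%]",
            f"  ensemble minimum change: {self.min_ensemble_pct_change:+.1f}%",
        ]
        if self.undefined_change:
            lines.append("  note: zero current total in some draws; change undefined there")
        mode = self.params.colonization_mode
        cur = self.colonized.loc[self.colonized["scenario"] == "current", "colonized_lakes"]
        lines.append(f"  colonized lakes (mode={mode}): current {float(cur.iloc[0]):,.1f}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "current_total_ch4_kg": self.current_total_ch4_kg,
            "current_total_co2eq_kg": self.current_total_co2eq_kg,
            "future_total_ch4_kg_quantiles": list(self.future_total_ch4_kg_quantiles),
            "pct_change_quantiles": list(self.pct_change_quantiles),
            "min_ensemble_pct_change": self.min_ensemble_pct_change,
            "per_scenario": self.per_scenario.to_dict(orient="records"),
            "colonized": self.colonized.to_dict(orient="records"),
            "undefined_change": self.undefined_change,
            "n_mc": self.n_mc,
        }
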