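"""Synthetic inputs for every pipeline stage, under a seeded RNG contract.

Each generator emulates one class of raw data the analysis consumes:

* ``gen_incubation`` — headspace concentration time series from a forward
  simulation of sealed-jar gas accumulation with the inject/homogenize/
  withdraw sampling events applied, so recorded concentrations reflect the
  post-injection mixing state.
* ``gen_eems`` — trilinear fluorescence cubes built from five Gaussian
  fluorophores with treatment-structured scores, multiplicative noise and
  optional inner-filter attenuation from a CDOM-like absorbance spectrum.
* ``gen_qpcr`` — a serial-dilution standard set and unknown wells with
  replicate Ct values from the log-linear standard-curve model.
* ``gen_lakes`` — a lake table with log-normal surface areas and
  beta-distributed occurrence probabilities per climate scenario.

Every generator stores the underlying truth (cumulative production,
component scores, copy numbers) alongside its output so downstream recovery
tests never have to re-derive it, and is byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eem import EX_GRID_NM, EM_GRID_NM, DEFAULT_REFERENCE, EEMCube, ReferenceSpectra
from .gasflux import HeadspaceSeries, JarSpec, mass_to_ppm

__all__ = ["SynthConfig", "gen_incubation", "gen_eems", "gen_qpcr", "gen_lakes"]

GCMS = ("canESM2", "hadGEM2-ES", "CESM1-CAM5", "MIROC-ESM-CHEM", "composite-AR5")
RCPS = ("2.6", "4.5", "8.5")


def _default_scenarios() -> list[tuple[str, str]]:
    return [(g, r) for g in GCMS for r in RCPS]


def _default_production_means() -> dict[str, float]:
    # mg CH4 m^-2 over 150 d; TYP and DEC as reported, CON and CTR from the
    # reported fold ratios (TYP ~400x CON, ~1400x CTR, ~2745x DEC)
    return {
        "TYP": 7.22e3,
        "DEC": 2.63,
        "CON": 7.22e3 / 400.0,
        "CTR": 7.22e3 / 1400.0,
    }


def _default_spike_multipliers() -> dict[str, float]:
    # spike doubles production in TYP, strongly raises CTR, leaves the
    # phenol-inhibited forest-litter sediments unchanged
    return {"TYP": 2.0, "DEC": 1.0, "CON": 1.0, "CTR": 4.0}


def _default_copies() -> dict[str, float]:
    # mcrA copies per g dry weight; TYP anchor with the reported fold-deficits
    return {
        "TYP": 1e8,
        "CON": 1e8 / 1.72e2,
        "DEC": 1e8 / 1.33e4,
        "CTR": 1e8 / 1.4e3,
    }


@dataclass
class SynthConfig:
    """Study-design parameters shared by all generators.

    Defaults mirror the incubation design: four replicate jars per
    amendment (CTR, CON, DEC, TYP) x spike combination, organic-matter
    levels of 10/20/40%, a 150-day sampling window, and treatment
    production means set by the reported rates and fold ratios.
    """

    seed: int = 0
    n_replicates: int = 4
    treatments: list[str] = field(default_factory=lambda: ["CTR", "CON", "DEC", "TYP"])
    spike_arms: list[bool] = field(default_factory=lambda: [False, True])
    om_levels: list[float] = field(default_factory=lambda: [0.10, 0.20, 0.40])
    production_means: dict[str, float] = field(default_factory=_default_production_means)
    spike_multipliers: dict[str, float] = field(default_factory=_default_spike_multipliers)
    sampling_days: list[int] = field(
        default_factory=lambda: [7, 14, 21, 30, 45, 60, 80, 100, 120, 150]
    )
    jar_cv: float = 0.15          # between-jar lognormal CV of true totals
    gas_noise: float = 0.0        # relative sd on recorded concentrations
    logistic_plateau: float = 0.99  # fraction of asymptote reached at day 150

    eem_noise: float = 0.01       # relative intensity sd
    # measured EEMs carry inner-filter attenuation; the pipeline's correction
    # step undoes it, so the realistic default simulates it
    eem_inner_filter: bool = True
    eem_scatter: bool = False     # add first-order Rayleigh ridges

    ct_sd: float = 0.2            # Ct replicate sd for unknowns
    ct_sd_standards: float = 0.3  # Ct replicate sd for the dilution series
    curve_slope: float = -3.391   # Ct per log10 copies (efficiency ~ 0.972)
    curve_intercept: float = 38.0
    copies_gdw: dict[str, float] = field(default_factory=_default_copies)

    n_lakes: int = 500
    area_range_km2: tuple[float, float] = (0.1, 1000.0)
    scenario_labels: list[tuple[str, str]] = field(default_factory=_default_scenarios)
    occupancy_uplift: dict[str, float] = field(
        default_factory=lambda: {"2.6": 1.4, "4.5": 1.75, "8.5": 2.2}
    )

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if any(m < 0 for m in self.production_means.values()):
            raise ValueError("production means must be nonnegative")
        days = list(self.sampling_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling days must be strictly increasing")
        if days[-1] != 150:
            raise ValueError("the final sampling day must be 150")
        lo, hi = self.area_range_km2
        if not (0 < lo < hi):
            raise ValueError("area range must be positive and ordered")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# incubation headspace series
# ---------------------------------------------------------------------------

def _logistic_fraction(t: np.ndarray, plateau: float) -> np.ndarray:
    """Normalized saturating curve: 0 at day 0, exactly 1 at day 150.

    A logistic with midpoint at day 75 whose steepness puts the raw curve at
    ``plateau`` (default 99%) of its asymptote by day 150, then normalized so
    the stored day-150 truth is reached exactly.
    """
    k = np.log(plateau / (1 - plateau)) / 75.0
    s = 1.0 / (1.0 + np.exp(-k * (np.asarray(t, float) - 75.0)))
    s0 = 1.0 / (1.0 + np.exp(k * 75.0))
    s150 = 1.0 / (1.0 + np.exp(-k * 75.0))
    return (s - s0) / (s150 - s0)


def gen_incubation(
    config: SynthConfig, jar: JarSpec | None = None
) -> tuple[list[HeadspaceSeries], pd.DataFrame]:
    """Forward-simulate headspace series for the full jar design.

    Per jar, cumulative true production follows the saturating curve and
    reaches the jar's true total exactly at day 150.  At each sampling day
    the event bookkeeping (inject N2, homogenize, withdraw an aliquot) is
    applied to the simulated headspace mass, so the recorded ppm values are
    in the diluted mixed state.  CO2 production is simulated at a common
    rate across amendments (decomposition proceeds regardless of
    methanogenesis inhibition).

    Returns the series list and a truth table with each jar's true total
    (mg and mg m^-2).
    """
    jar = jar or JarSpec()
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.sampling_days, float)
    frac = _logistic_fraction(days, config.logistic_plateau)
    area_m2 = jar.sediment_area_m2

    co2_mean = 2.0e4  # mg CO2 m^-2 per 150 d, common across amendments
    series: list[HeadspaceSeries] = []
    truth_rows = []
    for om in config.om_levels:
        for treatment in config.treatments:
            for spike in config.spike_arms:
                if spike and om != 0.20:
                    continue  # the spike arm duplicates only the 20% OM setup
                for rep in range(1, config.n_replicates + 1):
                    jar_id = f"{treatment}-{int(om * 100)}-{'S' if spike else 'N'}-{rep}"
                    mult = config.spike_multipliers.get(treatment, 1.0) if spike else 1.0
                    mean = config.production_means[treatment] * mult
                    for gas, gmean in (("CH4", mean), ("CO2", co2_mean)):
                        if config.jar_cv > 0 and gmean > 0:
                            sigma = np.sqrt(np.log1p(config.jar_cv**2))
                            total_rate = gmean * rng.lognormal(-0.5 * sigma**2, sigma)
                        else:
                            rng.lognormal(0, 1)  # keep the stream aligned
                            total_rate = gmean
                        cum_mg = total_rate * area_m2 * frac
                        ppm = _simulate_events(cum_mg, jar, gas)
                        if config.gas_noise > 0:
                            ppm = ppm * (
                                1.0 + config.gas_noise * rng.standard_normal(len(ppm))
                            )
                            ppm = np.clip(ppm, 0.0, None)
                        else:
                            rng.standard_normal(len(ppm))
                        series.append(
                            HeadspaceSeries(
                                jar_id=jar_id,
                                treatment=treatment,
                                om_frac=om,
                                spike=spike,
                                gas=gas,
                                days=days,
                                ppm=ppm,
                            )
                        )
                        truth_rows.append(
                            {
                                "jar_id": jar_id,
                                "treatment": treatment,
                                "om_frac": om,
                                "spike": spike,
                                "gas": gas,
                                "true_total_mg": total_rate * area_m2,
                                "true_rate_mg_m2": total_rate,
                            }
                        )
    return series, pd.DataFrame(truth_rows)


def _simulate_events(cum_mass_mg: np.ndarray, jar: JarSpec, gas: str) -> np.ndarray:
    """Push a cumulative-production trajectory through the sampling events."""
    volume = jar.headspace_volume_mL
    remaining = 0.0
    produced_so_far = 0.0
    ppm = np.empty(len(cum_mass_mg))
    for k, cum in enumerate(cum_mass_mg):
        mass = remaining + (cum - produced_so_far)
        produced_so_far = cum
        mixed_volume = volume + jar.inject_mL
        ppm[k] = mass_to_ppm(mass, mixed_volume, jar.temperature_C, jar.pressure_kPa, gas)
        removed = mass * jar.withdraw_mL / mixed_volume
        remaining = mass - removed
        volume = volume + jar.inject_mL - jar.withdraw_mL
    return ppm


# ---------------------------------------------------------------------------
# fluorescence EEMs
# ---------------------------------------------------------------------------

# mean component scores per treatment: (humic1, humic2, tryptophan, tyrosine,
# phenol-leachate); phenol leachate lowest in TYP, highest in DEC, absent in CTR
_SCORE_MEANS = {
    "CTR": (2.0, 1.5, 1.0, 0.8, 0.0),
    "CON": (5.0, 4.0, 2.0, 1.5, 3.0),
    "DEC": (6.0, 5.0, 2.5, 2.0, 6.0),
    "TYP": (4.0, 3.0, 3.5, 2.5, 0.8),
}

_DOC_MEANS = {"CTR": 5.0, "CON": 25.0, "DEC": 35.0, "TYP": 30.0}


def gen_eems(
    config: SynthConfig,
    reference: ReferenceSpectra = DEFAULT_REFERENCE,
) -> tuple[EEMCube, pd.DataFrame]:
    """Generate porewater EEMs as noisy trilinear mixtures of the references.

    Each sample EEM is sum_f score_f * ex_profile_f (x) em_profile_f with
    Gaussian spectral profiles at the reference peaks.  Scores are
    nonnegative with treatment structure (phenol leachate absent in CTR,
    lowest in TYP, highest in DEC).  Multiplicative noise at ``eem_noise``;
    optional inner-filter attenuation from a CDOM-like exponential
    absorbance spectrum (the correction's exact inverse); optional Rayleigh
    scatter ridges.  One sample per (treatment, OM level, replicate).

    Returns the cube and a truth table of the simulated scores.
    """
    rng = np.random.default_rng(config.seed + 1)
    ex_prof, em_prof = reference.profiles(EX_GRID_NM, EM_GRID_NM)

    ids, data, scores_rows, docs, absorbances = [], [], [], [], []
    abs_nm = np.arange(250.0, 601.0, 2.0)
    n_samples = 0
    for om in config.om_levels:
        for treatment in config.treatments:
            means = np.asarray(_SCORE_MEANS[treatment], float)
            if reference.n_components != len(means):
                # custom reference sets reuse the leading treatment means
                means = np.resize(means, reference.n_components)
            base = means * (om / 0.20)
            for rep in range(1, config.n_replicates + 1):
                scores = base * rng.lognormal(0.0, 0.25, size=reference.n_components)
                scores[base == 0] = 0.0
                eem = np.einsum("f,jf,kf->jk", scores, ex_prof, em_prof)
                if config.eem_noise > 0:
                    eem = eem * (1.0 + config.eem_noise * rng.standard_normal(eem.shape))
                    np.clip(eem, 0.0, None, out=eem)
                else:
                    rng.standard_normal(eem.shape)
                doc = _DOC_MEANS[treatment] * (om / 0.20) * rng.lognormal(0.0, 0.1)
                a350 = 0.004 * doc
                absorb = a350 * np.exp(-0.018 * (abs_nm - 350.0))
                if config.eem_inner_filter:
                    a_ex = np.interp(EX_GRID_NM, abs_nm, absorb)
                    a_em = np.interp(EM_GRID_NM, abs_nm, absorb)
                    eem = eem * 10.0 ** (-(a_ex[:, None] + a_em[None, :]) / 2.0)
                if config.eem_scatter:
                    ridge = np.abs(EM_GRID_NM[None, :] - EX_GRID_NM[:, None]) <= 10.0
                    eem = eem + ridge * (0.5 * eem.max())
                sid = f"{treatment}-{int(om * 100)}-{rep}"
                ids.append(sid)
                data.append(eem)
                docs.append(doc)
                absorbances.append(absorb)
                scores_rows.append(
                    {"sample_id": sid, "treatment": treatment, "om_frac": om}
                    | {f"score_{lab}": s for lab, s in zip(reference.labels, scores)}
                )
                n_samples += 1
    if n_samples < 6:
        raise ValueError("need at least 6 samples (split-half requires two halves)")
    cube = EEMCube(
        sample_ids=ids,
        ex_nm=EX_GRID_NM.copy(),
        em_nm=EM_GRID_NM.copy(),
        data=np.stack(data),
        absorbance_nm=abs_nm,
        absorbance=np.stack(absorbances),
        doc_mg_l=np.asarray(docs),
    )
    return cube, pd.DataFrame(scores_rows)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def gen_qpcr(
    config: SynthConfig,
    standard_top_copies: float = 1e8,
    n_standards: int = 7,
    norm: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a qPCR plate: a 10-fold dilution standard set plus unknowns.

    Ct values follow the log-linear model
    ``Ct = intercept + slope * log10(copies) + Normal(0, sd)`` with the
    configured slope/intercept (defaults give ~97.2% amplification
    efficiency).  Unknown treatment abundances default to the configured
    copies-per-gram values, whose CON and DEC defaults sit at fold-deficits
    of 1.72e2 and 1.33e4 relative to TYP.  One pooled sample per
    (treatment, OM level), run in triplicate.

    Returns (plate table, truth table of true copy numbers).
    """
    rng = np.random.default_rng(config.seed + 2)
    norm = norm or {"elution_uL": 100.0, "template_uL": 2.0, "dry_mass_g": 0.25, "yield_frac": 1.0}
    rows = []
    # standards: known copies per reaction, 10-fold steps
    for level in range(n_standards):
        copies = standard_top_copies / 10.0**level
        ct0 = config.curve_intercept + config.curve_slope * np.log10(copies)
        for rep in range(1, 4):
            noise = rng.standard_normal()
            ct = ct0 + (config.ct_sd_standards * noise if config.ct_sd_standards > 0 else 0.0)
            rows.append(
                {
                    "well_type": "standard",
                    "sample_id": f"STD-{level + 1}",
                    "treatment": "",
                    "om_frac": np.nan,
                    "known_copies": copies,
                    "replicate": rep,
                    "ct": ct,
                }
            )
    # unknowns: copies per gdw -> copies per reaction via the normalization
    rxn_factor = norm["dry_mass_g"] * norm["yield_frac"] / (norm["elution_uL"] / norm["template_uL"])
    truth_rows = []
    for om in config.om_levels:
        for treatment in config.treatments:
            gdw = config.copies_gdw[treatment] * (om / 0.20)
            copies_rxn = gdw * rxn_factor
            ct0 = config.curve_intercept + config.curve_slope * np.log10(copies_rxn)
            sid = f"{treatment}-{int(om * 100)}"
            for rep in range(1, 4):
                noise = rng.standard_normal()
                ct = ct0 + (config.ct_sd * noise if config.ct_sd > 0 else 0.0)
                rows.append(
                    {
                        "well_type": "unknown",
                        "sample_id": sid,
                        "treatment": treatment,
                        "om_frac": om,
                        "known_copies": np.nan,
                        "replicate": rep,
                        "ct": ct,
                    }
                )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "treatment": treatment,
                    "om_frac": om,
                    "true_copies_gdw": gdw,
                    "true_copies_rxn": copies_rxn,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# lake scenario table
# ---------------------------------------------------------------------------

def gen_lakes(config: SynthConfig) -> pd.DataFrame:
    """Generate a Boreal-Shield-like lake table with occurrence scenarios.

    Surface areas are log-normal (log10 area ~ Normal(-0.5, 0.8)) truncated
    to the configured range, putting most mass at small lakes.  Current
    occurrence probabilities are beta-distributed (most lakes unlikely to
    host emergent macrophytes today); each future (GCM, RCP) column applies
    an RCP-specific mean uplift with GCM-level and lake-level spread, so
    future probabilities are stochastically at least the current ones on
    average, clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed + 3)
    lo, hi = config.area_range_km2
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    n = config.n_lakes
    log_area = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(-0.5, 0.8, size=2 * (n - filled))
        draw = draw[(draw >= log_lo) & (draw <= log_hi)]
        take = min(len(draw), n - filled)
        log_area[filled : filled + take] = draw[:take]
        filled += take
    area = 10.0**log_area
    p_current = rng.beta(1.2, 4.0, size=n)
    df = pd.DataFrame(
        {
            "lake_id": [f"L{i + 1:05d}" for i in range(n)],
            "area_km2": area,
            "p_current": p_current,
        }
    )
    for gcm, rcp in config.scenario_labels:
        gcm_mult = rng.lognormal(0.0, 0.08)
        lake_mult = rng.lognormal(0.0, 0.15, size=n)
        uplift = config.occupancy_uplift.get(rcp, 1.5)
        df[f"p_{gcm}_rcp{rcp}"] = np.clip(p_current * uplift * gcm_mult * lake_mult, 0.0, 1.0)
    return df
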