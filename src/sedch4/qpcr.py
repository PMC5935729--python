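"""Absolute qPCR quantification of the mcrA methanogen marker gene.

A serial-dilution standard relates quantification cycle (Ct) to template
copies through the log-linear model ``Ct = intercept + slope * log10(copies)``;
amplification efficiency is ``E = 10**(-1/slope) - 1``.  Unknown samples are
quantified from their mean triplicate Ct, normalized to copies per gram of
dry sediment (elution volume / template volume / dry mass / extraction
yield), and compared across treatments as geometric-mean fold differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Normalization",
    "StandardCurveModel",
    "StandardCurveResults",
    "quantify",
    "fold_table",
]


@dataclass(frozen=True)
class Normalization:
    """Per-sample bookkeeping from reaction to sediment dry weight.

    copies_gdw = copies_rxn * (elution/template) / (dry_mass * yield).
    """

    elution_uL: float = 100.0
    template_uL: float = 2.0
    dry_mass_g: float = 0.25
    yield_frac: float = 1.0

    def __post_init__(self) -> None:
        if min(self.elution_uL, self.template_uL, self.dry_mass_g, self.yield_frac) <= 0:
            raise ValueError("normalization factors must be positive")

    @property
    def factor(self) -> float:
        return (self.elution_uL / self.template_uL) / (self.dry_mass_g * self.yield_frac)


class StandardCurveModel:
    """Ordinary least squares of mean Ct on log10 template copies.

    Parameters
    ----------
    copies:
        Known copy numbers of the dilution points (>= 3 points spanning at
        least two orders of magnitude).
    cts:
        Replicate Ct values per dilution point (list of arrays, or a 2-D
        array with replicates along the second axis); replicates are
        averaged before the regression.
    """

    def __init__(self, copies, cts):
        copies = np.asarray(copies, dtype=float)
        mean_ct = np.array([np.mean(np.asarray(c, dtype=float)) for c in cts])
        if copies.ndim != 1 or len(copies) != len(mean_ct):
            raise ValueError("copies and cts must align one Ct set per dilution point")
        if len(copies) < 3:
            raise ValueError("need at least 3 dilution points")
        if np.any(copies <= 0):
            raise ValueError("copy numbers must be positive")
        logc = np.log10(copies)
        if logc.max() - logc.min() < 2.0:
            raise ValueError("dilution series must span at least two orders of magnitude")
        self.log_copies = logc
        self.mean_ct = mean_ct

    def fit(self) -> "StandardCurveResults":
        ols = sm.OLS(self.mean_ct, sm.add_constant(self.log_copies)).fit()
        intercept, slope = ols.params
        if slope >= 0:
            raise ValueError("standard-curve slope must be negative (assay inversion?)")
        return StandardCurveResults(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(ols.rsquared),
            n_points=len(self.log_copies),
            log_copies_range=(float(self.log_copies.min()), float(self.log_copies.max())),
            _ols=ols,
        )


@dataclass
class StandardCurveResults:
    """Fitted standard curve: slope, intercept, R^2 and derived efficiency."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    log_copies_range: tuple[float, float]
    _ols: object = field(default=None, repr=False)

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, E = 10**(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies_from_ct(self, ct: float | np.ndarray) -> float | np.ndarray:
        """Invert the curve; warns when extrapolating beyond the standards."""
        logc = (np.asarray(ct, dtype=float) - self.intercept) / self.slope
        lo, hi = self.log_copies_range
        if np.any(logc < lo) or np.any(logc > hi):
            warnings.warn(
                "Ct outside the standard-curve range; extrapolating",
                stacklevel=2,
            )
        out = 10.0**logc
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        return (
            "qPCR standard curve (OLS of mean Ct on log10 copies)\n"
            f"  slope:      {self.slope:.4f} Ct per log10 copies\n"
            f"  intercept:  {self.intercept:.3f} Ct\n"
            f"  R^2:        {self.r_squared:.4f}\n"
            f"  efficiency: {self.efficiency:.1%}\n"
            f"  points:     {self.n_points} spanning 10^{self.log_copies_range[0]:.1f}"
            f"-10^{self.log_copies_range[1]:.1f} copies"
        )


def fit_plate_standards(plate: pd.DataFrame) -> StandardCurveResults:
    """Fit the standard curve from a plate table (synth CSV format)."""
    std = plate[plate["well_type"] == "standard"]
    grouped = std.groupby("known_copies", sort=True)["ct"]
    copies = np.array(sorted(grouped.groups))
    cts = [grouped.get_group(c).to_numpy() for c in copies]
    return StandardCurveModel(copies, cts).fit()


def quantify(
    curve: StandardCurveResults,
    unknowns: pd.DataFrame,
    norm: Normalization | None = None,
) -> pd.DataFrame:
    """Quantify unknown samples from triplicate Cts.

    ``unknowns`` must carry sample_id, replicate ct values (column ``ct``)
    and optionally treatment/om_frac metadata.  Returns one row per sample
    with mean Ct, copies per reaction and copies per gram dry weight.
    """
    norm = norm or Normalization()
    rows = []
    meta_cols = [c for c in ("treatment", "om_frac") if c in unknowns.columns]
    for sid, g in unknowns.groupby("sample_id", sort=True):
        mean_ct = float(g["ct"].mean())
        copies_rxn = curve.copies_from_ct(mean_ct)
        row = {
            "sample_id": sid,
            "mean_ct": mean_ct,
            "n_replicates": len(g),
            "copies_rxn": copies_rxn,
            "copies_gdw": copies_rxn * norm.factor,
        }
        for c in meta_cols:
            row[c] = g[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def fold_table(results: pd.DataFrame, reference_label: str) -> pd.DataFrame:
    """Treatment fold differences vs a reference, geometric across %OM levels.

    For each treatment the fold vs the reference treatment is computed
    within each OM level, then combined as a geometric mean (abundances
    span orders of magnitude); the SE is computed on the log10 scale across
    OM levels and back-transformed.  ``fold_deficit`` is reference/treatment.
    """
    if reference_label not in set(results["treatment"]):
        raise ValueError(f"reference treatment {reference_label!r} not present")
    ref = results[results["treatment"] == reference_label].set_index("om_frac")["copies_gdw"]
    rows = []
    for treatment, g in results.groupby("treatment", sort=True):
        g = g.set_index("om_frac")
        common = g.index.intersection(ref.index)
        folds = (g.loc[common, "copies_gdw"] / ref.loc[common]).to_numpy(float)
        logf = np.log10(folds)
        gm = 10.0 ** logf.mean()
        se_log = logf.std(ddof=1) / np.sqrt(len(logf)) if len(logf) > 1 else 0.0
        rows.append(
            {
                "treatment": treatment,
                "n_om_levels": len(folds),
                "fold_vs_reference": gm,
                "fold_deficit": 1.0 / gm if gm > 0 else np.inf,
                "fold_se_factor": 10.0**se_log,
            }
        )
    return pd.DataFrame(rows)
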