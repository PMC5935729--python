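"""Statistical layer: amendment x spike ANOVA and the log-log phenol model.

Two analyses link the incubation outputs: a one-way ANOVA over the eight
amendment x spike cells at a single organic-matter level (with pairwise
group separation obtained by re-levelling the baseline), and a log-log
regression of CH4 production on the relative phenol index, whose slope is
the elasticity of production with respect to phenols and is expected to be
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AmendmentAnova",
    "AnovaResults",
    "LogLogModel",
    "LogLogResults",
]


class AmendmentAnova:
    """One-way ANOVA of production over amendment x spike cells.

    Parameters
    ----------
    table:
        Long table with columns ``treatment``, ``spike``, ``om_frac`` and the
        response (default ``rate_mg_m2``); one row per jar.
    om_level:
        The organic-matter fraction to analyse (the design repeats the
        ANOVA per OM level).
    log_scale:
        Analyse log-transformed production (default True: production spans
        orders of magnitude so raw-scale homoscedasticity is untenable).
        Zero or negative responses are offset by half the smallest positive
        value before the log.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        om_level: float,
        response: str = "rate_mg_m2",
        log_scale: bool = True,
        alpha: float = 0.05,
    ):
        df = table[np.isclose(table["om_frac"], om_level)].copy()
        if df.empty:
            raise ValueError(f"no rows at OM level {om_level}")
        df["cell"] = df["treatment"].astype(str) + np.where(df["spike"], "+spike", "")
        counts = df.groupby("cell")[response].count()
        if (counts < 2).any():
            bad = list(counts[counts < 2].index)
            raise ValueError(f"cells with fewer than 2 replicates: {bad}")
        y = df[response].to_numpy(float)
        if log_scale:
            if np.any(y <= 0):
                offset = 0.5 * y[y > 0].min()
                y = y + offset
            y = np.log(y)
        df["_y"] = y
        self.data = df
        self.om_level = om_level
        self.log_scale = log_scale
        self.alpha = alpha

    def fit(self) -> "AnovaResults":
        model = smf.ols("_y ~ C(cell)", data=self.data).fit()
        aov = sm.stats.anova_lm(model, typ=1)
        f_stat = float(aov.loc["C(cell)", "F"])
        df_b = int(aov.loc["C(cell)", "df"])
        df_w = int(aov.loc["Residual", "df"])
        p = float(aov.loc["C(cell)", "PR(>F)"])

        cells = sorted(self.data["cell"].unique())
        means = self.data.groupby("cell")["_y"].mean()
        pair_p = self._pairwise_p(cells)
        labels = self._group_labels(cells, means, pair_p)
        return AnovaResults(
            f_statistic=f_stat,
            df_between=df_b,
            df_within=df_w,
            p_value=p,
            cell_means=means,
            pairwise_p=pair_p,
            group_labels=labels,
            log_scale=self.log_scale,
            om_level=self.om_level,
        )

    def _pairwise_p(self, cells) -> pd.DataFrame:
        """p-values for all cell pairs via baseline re-levelling.

        Re-fitting with each cell as the baseline reads every pairwise
        difference off the coefficient table of the cell-means model with a
        pooled error term, exactly as comparing groups by adjusting the
        intercept group.
        """
        out = pd.DataFrame(np.ones((len(cells), len(cells))), index=cells, columns=cells)
        for base in cells:
            model = smf.ols(
                f"_y ~ C(cell, Treatment(reference={base!r}))", data=self.data
            ).fit()
            for name, p in model.pvalues.items():
                if name == "Intercept":
                    continue
                other = name.split("[T.")[1].rstrip("]")
                out.loc[base, other] = p
                out.loc[other, base] = p
        return out

    def _group_labels(self, cells, means, pair_p) -> dict[str, int]:
        """Number groups by merging cells not significantly different.

        Cells are nodes; an edge joins pairs with p >= alpha; connected
        components become numbered groups, ordered by descending group mean
        (ties by cell name).
        """
        parent = {c: c for c in cells}

        def find(c):
            while parent[c] != c:
                parent[c] = parent[parent[c]]
                c = parent[c]
            return c

        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                # NaN p (e.g. zero residual variance) cannot separate a pair
                if not (pair_p.loc[a, b] < self.alpha):
                    parent[find(a)] = find(b)
        comps: dict[str, list[str]] = {}
        for c in cells:
            comps.setdefault(find(c), []).append(c)
        ordered = sorted(
            comps.values(), key=lambda grp: (-np.mean([means[c] for c in grp]), grp[0])
        )
        return {c: i + 1 for i, grp in enumerate(ordered) for c in grp}


@dataclass
class AnovaResults:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    cell_means: pd.Series
    pairwise_p: pd.DataFrame
    group_labels: dict[str, int]
    log_scale: bool
    om_level: float

    def summary(self) -> str:
        scale = "log" if self.log_scale else "raw"
        lines = [
            f"One-way ANOVA over amendment x spike cells ({scale} scale, "
            f"OM {self.om_level:.0%})",
            f"  F({self.df_between}, {self.df_within}) = {self.f_statistic:.2f}, "
            f"p = {self.p_value:.3g}",
            "",
            "  cell          mean    group",
        ]
        for cell in self.cell_means.sort_values(ascending=False).index:
            lines.append(
                f"  {cell:<12s}{self.cell_means[cell]:>8.3f}    {self.group_labels[cell]}"
            )
        return "\n".join(lines)


class LogLogModel:
    """Log-log regression of CH4 production on the relative phenol index.

    Rows with nonpositive production or index are excluded (the log is
    undefined there; un-amended controls with zero phenol signal fall out
    naturally, so the fit spans the amended sediments).  Natural logs are
    used internally; the slope is base-invariant.
    """

    def __init__(self, phenol_index, production):
        x = np.asarray(phenol_index, dtype=float)
        y = np.asarray(production, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("phenol index and production must be equal-length 1-D")
        keep = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 3:
            raise ValueError("need at least 3 strictly positive (x, y) pairs")
        self.n_excluded = int((~keep).sum())
        self.log_x = np.log(x[keep])
        self.log_y = np.log(y[keep])

    def fit(self, conf_level: float = 0.95) -> "LogLogResults":
        ols = sm.OLS(self.log_y, sm.add_constant(self.log_x)).fit()
        ci = ols.conf_int(alpha=1 - conf_level)
        grid = np.linspace(self.log_x.min(), self.log_x.max(), 100)
        pred = ols.get_prediction(sm.add_constant(grid)).summary_frame(
            alpha=1 - conf_level
        )
        band = pd.DataFrame(
            {
                "phenol_index": np.exp(grid),
                "fit": np.exp(pred["mean"].to_numpy()),
                "lower": np.exp(pred["mean_ci_lower"].to_numpy()),
                "upper": np.exp(pred["mean_ci_upper"].to_numpy()),
            }
        )
        return LogLogResults(
            intercept=float(ols.params[0]),
            slope=float(ols.params[1]),
            intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
            slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
            r_squared=float(ols.rsquared),
            n_obs=int(ols.nobs),
            n_excluded=self.n_excluded,
            conf_level=conf_level,
            band=band,
            _ols=ols,
        )


@dataclass
class LogLogResults:
    """Power-law fit log(production) = b0 + b1 log(index) with CIs and band."""

    intercept: float
    slope: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    r_squared: float
    n_obs: int
    n_excluded: int
    conf_level: float
    band: pd.DataFrame
    _ols: object = field(default=None, repr=False)

    def summary(self) -> str:
        lo, hi = self.slope_ci
        ilo, ihi = self.intercept_ci
        return (
            "Log-log model: log(CH4 production) ~ log(phenol index)\n"
            f"  slope (elasticity): {self.slope:.3f}  "
            f"[{lo:.3f}, {hi:.3f}] {self.conf_level:.0%} CI\n"
            f"  intercept:          {self.intercept:.3f}  [{ilo:.3f}, {ihi:.3f}]\n"
            f"  R^2: {self.r_squared:.3f}   n = {self.n_obs} "
            f"({self.n_excluded} nonpositive rows excluded)"
        )

    def plot(self, ax=None):
        """Fitted power law with its mean-prediction band, log-log axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.band["phenol_index"], self.band["fit"], color="C0")
        ax.fill_between(
            self.band["phenol_index"],
            self.band["lower"],
            self.band["upper"],
            alpha=0.3,
            color="C0",
        )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("relative phenol concentration")
        ax.set_ylabel("CH4 production (mg m$^{-2}$)")
        return ax
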