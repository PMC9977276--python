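"""Quantification of diazotrophic phenotype measurements.

Three measurement classes are modeled:

* OD600 growth time series, fitted to the logistic model
  ``N(t) = K / (1 + ((K - N0)/N0) * exp(-r t))`` with carrying capacity K,
  intrinsic rate r (1/hr) and inoculum N0 — the parametrization used by
  standard microbial growth-curve fitting.  Derived quantities are the
  doubling time ``ln 2 / r`` and the sigmoid midpoint
  ``t_mid = ln((K - N0)/N0) / r``.
* Product-accumulation assays (e.g. ethylene from acetylene reduction):
  ordinary least-squares slope of product vs time, normalized to total
  protein, with the slope's standard error propagated.
* Group comparisons by one-way ANOVA with post-hoc Tukey HSD (Tukey-Kramer
  for unequal replicate counts), and the H2-formed / N2-reduced catalytic
  efficiency ratio with its mechanistic floor of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurveData",
    "GrowthFit",
    "LogisticGrowthModel",
    "fit_logistic",
    "logistic",
    "reduction_rate",
    "RateEstimate",
    "AssayTable",
    "anova_tukey",
    "AnovaTukeyResult",
    "efficiency_ratio",
    "EfficiencyRatio",
]

EFFICIENCY_FLOOR = 1.0  # stoichiometric minimum of the reductive-elimination mechanism


def logistic(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """Logistic growth N(t) with carrying capacity K, rate r, inoculum N0."""
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * np.asarray(t, dtype=float)))


@dataclass
class GrowthCurveData:
    """One replicate growth series: strictly increasing times (hours), OD600 >= 0."""

    strain: str
    replicate: str | int
    time: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.time.shape != self.od600.shape or self.time.ndim != 1:
            raise ValueError("time and od600 must be 1-D and equally long")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"{self.strain}/{self.replicate}: times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError(f"{self.strain}/{self.replicate}: negative OD600")

    @staticmethod
    def from_frame(df: pd.DataFrame) -> list["GrowthCurveData"]:
        """Split a tidy (strain, replicate, time_h, od600) table into curves."""
        need = {"strain", "replicate", "time_h", "od600"}
        if not need <= set(df.columns):
            raise ValueError(f"growth table needs columns {sorted(need)}")
        out = []
        for (strain, rep), g in df.groupby(["strain", "replicate"], sort=True):
            g = g.sort_values("time_h")
            out.append(
                GrowthCurveData(str(strain), rep, g["time_h"].to_numpy(), g["od600"].to_numpy())
            )
        return out


@dataclass
class GrowthFit:
    """Fitted logistic parameters and derived times for one growth curve."""

    strain: str
    replicate: str | int
    K: float
    r: float
    N0: float
    residual_sd: float
    success: bool = True
    message: str = ""
    K_se: float = float("nan")
    r_se: float = float("nan")

    @property
    def doubling_time(self) -> float:
        """Exponential-phase doubling time, ln 2 / r (hours)."""
        return float(np.log(2.0) / self.r)

    @property
    def t_mid(self) -> float:
        """Time of the sigmoid midpoint N = K/2 (hours)."""
        return float(np.log((self.K - self.N0) / self.N0) / self.r)

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "replicate": self.replicate,
            "K": self.K,
            "r": self.r,
            "N0": self.N0,
            "doubling_time_h": self.doubling_time,
            "t_mid_h": self.t_mid,
            "residual_sd": self.residual_sd,
            "success": self.success,
        }


def fit_logistic(curve: GrowthCurveData) -> GrowthFit:
    """Nonlinear least-squares logistic fit of one OD600 series.

    Initialization: K from the maximum OD, N0 from the first positive OD,
    r from the log-OD slope over the middle rise.  Failure to converge, or
    an optimum with K <= N0, is returned flagged (``success=False``) with
    the optimizer's message — never silently.
    """
    t, y = curve.time, curve.od600
    if t.size < 5:
        raise ValueError(f"{curve.strain}/{curve.replicate}: need >= 5 time points, got {t.size}")
    K0 = float(y.max())
    positive = y[y > 0]
    if positive.size == 0 or K0 <= 0:
        return GrowthFit(curve.strain, curve.replicate, np.nan, np.nan, np.nan, np.nan,
                         success=False, message="no positive OD values")
    N00 = float(positive[0])
    # slope of log OD across the middle rise (between 20% and 80% of max)
    rise = (y > 0.2 * K0) & (y < 0.8 * K0) & (y > 0)
    if rise.sum() >= 2:
        r0 = float(np.polyfit(t[rise], np.log(y[rise]), 1)[0])
    else:
        r0 = 1.0 / max(t.max() - t.min(), 1e-6)
    r0 = max(r0, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                logistic,
                t,
                y,
                p0=[K0, r0, max(N00, 1e-6)],
                bounds=([1e-9, 1e-9, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        return GrowthFit(curve.strain, curve.replicate, np.nan, np.nan, np.nan, np.nan,
                         success=False, message=f"fit failed: {exc}")
    K, r, N0 = (float(v) for v in popt)
    resid = y - logistic(t, K, r, N0)
    dof = max(t.size - 3, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 3
    if K <= N0:
        return GrowthFit(curve.strain, curve.replicate, K, r, N0, residual_sd,
                         success=False, message=f"degenerate optimum: K={K:.4g} <= N0={N0:.4g}")
    return GrowthFit(curve.strain, curve.replicate, K, r, N0, residual_sd,
                     K_se=float(se[0]), r_se=float(se[1]))


class LogisticGrowthModel:
    """Logistic growth model over a set of replicate OD600 curves.

    ``fit()`` fits each replicate independently and returns a results object
    carrying per-replicate parameters and per-strain summaries.
    """

    def __init__(self, curves: Sequence[GrowthCurveData]) -> None:
        if not curves:
            raise ValueError("no growth curves")
        self.curves = list(curves)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LogisticGrowthModel":
        return cls(GrowthCurveData.from_frame(df))

    def fit(self) -> "LogisticGrowthResults":
        return LogisticGrowthResults(self, [fit_logistic(c) for c in self.curves])


class LogisticGrowthResults:
    """Per-replicate logistic fits with strain-level summaries."""

    def __init__(self, model: LogisticGrowthModel, fits: list[GrowthFit]) -> None:
        self.model = model
        self.fits = fits

    @property
    def converged(self) -> bool:
        return all(f.success for f in self.fits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.to_dict() for f in self.fits])

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD of doubling and midpoint times per strain."""
        df = self.to_frame()
        ok = df[df["success"]]
        return (
            ok.groupby("strain")
            .agg(
                n=("replicate", "size"),
                doubling_time_h=("doubling_time_h", "mean"),
                doubling_time_sd=("doubling_time_h", "std"),
                t_mid_h=("t_mid_h", "mean"),
                t_mid_sd=("t_mid_h", "std"),
                K=("K", "mean"),
                r=("r", "mean"),
            )
            .reset_index()
        )

    def plot(self, ax=None):  # pragma: no cover - thin plotting veneer
        """Overlay observed points and fitted curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for curve, f in zip(self.model.curves, self.fits):
            (pts,) = ax.plot(curve.time, curve.od600, ".", alpha=0.5)
            if f.success:
                tt = np.linspace(curve.time.min(), curve.time.max(), 200)
                ax.plot(tt, logistic(tt, f.K, f.r, f.N0), color=pts.get_color())
        ax.set_xlabel("time (h)")
        ax.set_ylabel("OD600")
        return ax


# ------------------------------------------------------------------ assays
@dataclass
class RateEstimate:
    """Protein-normalized product-formation rate with standard error."""

    rate: float  # e.g. umol C2H4 / mg protein / hr
    se: float
    slope: float
    slope_se: float
    n: int


def reduction_rate(
    times: np.ndarray, product_amount: np.ndarray, protein_mg: float
) -> RateEstimate:
    """OLS slope of product vs time (free intercept) per mg total protein.

    Times in hours, product in umol, protein in mg give umol/mg/hr.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(product_amount, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 time points, got {t.size}")
    if protein_mg <= 0:
        raise ValueError(f"protein mass must be positive, got {protein_mg}")
    res = stats.linregress(t, y)
    slope_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return RateEstimate(
        rate=float(res.slope) / protein_mg,
        se=slope_se / protein_mg,
        slope=float(res.slope),
        slope_se=slope_se,
        n=t.size,
    )


@dataclass
class AssayTable:
    """Replicate measurements per group, uniform units (tidy group/value)."""

    groups: list[str]
    values: list[np.ndarray]
    units: str = ""

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        if len(self.groups) != len(self.values):
            raise ValueError("groups and values differ in length")
        for g, v in zip(self.groups, self.values):
            if v.size < 1:
                raise ValueError(f"group {g!r} has no replicates")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, units: str = "") -> "AssayTable":
        if not {"group", "value"} <= set(df.columns):
            raise ValueError("assay table needs columns group, value")
        groups, values = [], []
        for g, sub in df.groupby("group", sort=True):
            groups.append(str(g))
            values.append(sub["value"].to_numpy(dtype=float))
        return cls(groups, values, units)


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F test plus all-pairs Tukey HSD adjusted p-values."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj
    degenerate: bool = False
    note: str = ""

    def significant_pairs(self, alpha: float = 0.01) -> pd.DataFrame:
        return self.pairwise[self.pairwise["p_adj"] < alpha]


def anova_tukey(table: AssayTable, pairwise: bool = True) -> AnovaTukeyResult:
    """Classical one-way ANOVA with post-hoc Tukey HSD.

    Pairwise p-values come from the studentized-range distribution
    (Tukey-Kramer adjustment under unequal replicate counts); pass
    ``pairwise=False`` to skip the post-hoc stage when only the omnibus
    F test is wanted (the studentized-range integration dominates the
    cost).  Two
    degenerate inputs are handled explicitly: all observations identical
    gives F = 0, p = 1 (flagged); zero within-group variance with unequal
    means gives p reported at its 0 limit (flagged).
    """
    if len(table.groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in zip(table.groups, table.values):
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates")
    vals = table.values
    means = np.array([v.mean() for v in vals])
    ns = np.array([v.size for v in vals])
    sse = float(sum(((v - v.mean()) ** 2).sum() for v in vals))
    df_within = int(ns.sum() - len(vals))

    pairs = []
    if sse == 0.0:
        if np.allclose(means, means[0]):
            for i in range(len(vals)):
                for j in range(i + 1, len(vals)):
                    pairs.append((table.groups[i], table.groups[j], 0.0, 1.0))
            return AnovaTukeyResult(0.0, 1.0, _pair_frame(pairs), degenerate=True,
                                    note="all observations identical")
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                diff = means[j] - means[i]
                pairs.append((table.groups[i], table.groups[j], diff,
                              0.0 if diff != 0 else 1.0))
        return AnovaTukeyResult(float("inf"), 0.0, _pair_frame(pairs), degenerate=True,
                                note="zero within-group variance with unequal means (p at 0 limit)")

    F, p = stats.f_oneway(*vals)
    ms_within = sse / df_within
    k = len(vals)
    if not pairwise:
        return AnovaTukeyResult(float(F), float(p), _pair_frame([]))
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = np.sqrt(ms_within * 0.5 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_within))
            pairs.append((table.groups[i], table.groups[j], float(diff), min(max(p_adj, 0.0), 1.0)))
    return AnovaTukeyResult(float(F), float(p), _pair_frame(pairs))


def _pair_frame(pairs: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=["group_a", "group_b", "mean_diff", "p_adj"])


# -------------------------------------------------------------- efficiency
@dataclass
class EfficiencyRatio:
    """H2-formed / N2-reduced catalytic efficiency (dimensionless).

    Ratios below the mechanistic floor of 1 are physically suspect and are
    flagged, not rejected.
    """

    ratio: float
    below_floor: bool
    floor: float = EFFICIENCY_FLOOR


def efficiency_ratio(
    h2_formed: float, n2_reduced: float, from_ammonia: bool = False
) -> EfficiencyRatio:
    """H2/N2 efficiency ratio; ``from_ammonia=True`` converts NH3 to N2 (/2)."""
    n2 = n2_reduced / 2.0 if from_ammonia else float(n2_reduced)
    if n2 <= 0:
        raise ValueError(f"N2 reduced must be positive, got {n2}")
    ratio = float(h2_formed) / n2
    return EfficiencyRatio(ratio=ratio, below_floor=ratio < EFFICIENCY_FLOOR)
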