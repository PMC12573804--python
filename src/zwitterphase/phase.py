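"""Phase-behaviour layer: regime classification and empirical copolymer laws.

Monomer interaction free energies map onto three phase-separation regimes
(no phase separation, liquid-liquid, liquid-gel) through configurable kBT
thresholds. For sticker-spacer copolymer series, two empirical linear laws
are fitted by ordinary least squares: sqrt(Cs,max) against the sticker
fraction f_sticker, and the cloud-point temperature Tcp against Cs,max.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import InteractionFreeEnergy

#: Default regime thresholds (kBT). Chosen to separate the observed groups
#: (no phase separation at <= 0.62 kBT, coacervates around 1 kBT, gel at
#: 2.77 kBT); the true boundaries also depend on polymer and salt
#: concentration, so these are configuration, never hard-coded downstream.
DEFAULT_THRESHOLDS: tuple[float, float] = (0.8, 2.0)


class PhaseRegime(enum.IntEnum):
    """Ordered phase-separation regimes (ordering supports monotonicity)."""

    NO_PHASE_SEPARATION = 0
    LIQUID_LIQUID = 1
    LIQUID_GEL = 2


def classify_regime(
    dg, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> PhaseRegime:
    """Map an interaction free energy (kBT) to a phase regime.

    Half-open assignment: value < t_low -> no phase separation;
    t_low <= value < t_high -> liquid-liquid; value >= t_high -> liquid-gel.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError(f"thresholds must satisfy t_low < t_high, got {thresholds}")
    value = dg.value if isinstance(dg, InteractionFreeEnergy) else float(dg)
    if value < t_low:
        return PhaseRegime.NO_PHASE_SEPARATION
    if value < t_high:
        return PhaseRegime.LIQUID_LIQUID
    return PhaseRegime.LIQUID_GEL


@dataclass
class CopolymerSeries:
    """Copolymer observations: sticker fraction, salt resistance, cloud point.

    ``data`` columns: label, f_sticker (fraction of sticker monomer, in
    [0, 1]), cs_max (maximum NaCl concentration with phase separation, M),
    tcp (cloud-point temperature, deg C; optional / NaN). ``metadata``
    records fixed conditions such as the polymer concentration (mg/mL) and
    NaCl background (mM).
    """

    data: pd.DataFrame
    metadata: dict | None = None

    def __post_init__(self):
        required = {"label", "f_sticker", "cs_max"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"copolymer table missing columns {sorted(missing)}")
        f = self.data["f_sticker"].to_numpy(float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("f_sticker must lie in [0, 1]")
        cs = self.data["cs_max"].to_numpy(float)
        if np.any(cs[np.isfinite(cs)] < 0):
            raise ValueError("cs_max must be non-negative")
        if "tcp" not in self.data.columns:
            self.data = self.data.assign(tcp=np.nan)


@dataclass(frozen=True)
class LinearFit:
    """OLS fit y = slope*x + intercept with standard diagnostics."""

    slope: float
    intercept: float
    stderr_slope: float
    resid_se: float
    r_squared: float
    n: int
    transform: str          # "sqrt_cs_on_f" or "tcp_on_cs"
    x_range: tuple[float, float]

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the slope."""
        half = stats.t.ppf(0.5 + level / 2, self.n - 2) * self.stderr_slope
        return (self.slope - half, self.slope + half)


def _ols(x: np.ndarray, y: np.ndarray, transform: str) -> LinearFit:
    if x.size < 3:
        raise ValueError(f"need at least 3 records for a fit, got {x.size}")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = x.size - 2
    resid_se = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else float("nan")
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        stderr_slope=float(res.stderr), resid_se=resid_se,
        r_squared=float(res.rvalue**2), n=int(x.size), transform=transform,
        x_range=(float(x.min()), float(x.max())),
    )


def fit_sqrt_salt_law(series: CopolymerSeries) -> LinearFit:
    """OLS of sqrt(Cs,max) on the sticker fraction f_sticker.

    The square-root transform is part of the law; :func:`predict_csmax`
    inverts it. No per-point weighting (no per-record uncertainties are
    recorded for these series).
    """
    df = series.data.dropna(subset=["cs_max"])
    cs = df["cs_max"].to_numpy(float)
    if np.any(cs < 0):
        raise ValueError("cs_max must be non-negative")
    return _ols(df["f_sticker"].to_numpy(float), np.sqrt(cs), "sqrt_cs_on_f")


def fit_tcp_csmax(series: CopolymerSeries) -> LinearFit:
    """OLS of the cloud-point temperature Tcp on Cs,max."""
    df = series.data.dropna(subset=["cs_max", "tcp"])
    return _ols(df["cs_max"].to_numpy(float), df["tcp"].to_numpy(float), "tcp_on_cs")


@dataclass(frozen=True)
class CsMaxPrediction:
    """Predicted maximum salt concentration (M) with boundary flags."""

    value: float
    clamped: bool
    extrapolated: bool


def predict_csmax(fit: LinearFit, f_sticker: float) -> CsMaxPrediction:
    """Invert the sqrt law: Cs,max = (slope*f + intercept)^2, clamped at 0.

    Flags mark a negative linear predictor (clamped to zero salt resistance)
    and extrapolation beyond the fitted f_sticker range.
    """
    if fit.transform != "sqrt_cs_on_f":
        raise ValueError("predict_csmax requires a fit from fit_sqrt_salt_law")
    if not 0.0 <= f_sticker <= 1.0:
        raise ValueError(f"f_sticker must lie in [0, 1], got {f_sticker}")
    lin = fit.slope * f_sticker + fit.intercept
    clamped = lin < 0
    extrapolated = not (fit.x_range[0] <= f_sticker <= fit.x_range[1])
    return CsMaxPrediction(value=0.0 if clamped else float(lin**2),
                           clamped=clamped, extrapolated=extrapolated)


def rank_correlation(dg_values, cs_values) -> tuple[float, float]:
    """Spearman rank correlation between interaction strength and Cs,max.

    Reported as a consistency statistic between the in-silico interaction
    free energies and the measured salt resistance; no functional form is
    imposed on that relation.
    """
    rho, p = stats.spearmanr(np.asarray(dg_values, float), np.asarray(cs_values, float))
    return float(rho), float(p)
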