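"""Contextual-effect statistics derived from fitted area-level variances.

Closed forms for the general contextual effect of areas in a two-level
logistic model with random-intercept variance tau^2:

* latent-variable ICC:  tau^2 / (tau^2 + pi^2/3), the share of latent-scale
  outcome variance attributable to areas (the logistic residual variance is
  pi^2/3);
* median odds ratio:  MOR = exp(sqrt(2 tau^2) * PHI^-1(0.75)), the median of
  the odds ratios comparing two identical persons from a higher- vs a
  lower-risk area; MOR = 1 means no area effect;
* proportional change in variance:  PCV = 100 (tau^2_model - tau^2_ref) /
  tau^2_ref against a reference (usually null) model — negative means
  variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "LOGISTIC_RESIDUAL_VARIANCE",
    "icc_latent",
    "median_odds_ratio",
    "pcv",
    "access_explained",
    "VarianceLadder",
    "ladder_summary",
]

#: Residual variance of the standard logistic distribution, pi^2 / 3.
LOGISTIC_RESIDUAL_VARIANCE = np.pi ** 2 / 3.0


def _check_tau2(tau2) -> np.ndarray:
    arr = np.asarray(tau2, float)
    if (arr < 0).any():
        raise ValueError("tau2 must be >= 0")
    return arr


def icc_latent(tau2):
    """Latent-variable intraclass correlation, tau^2 / (tau^2 + pi^2/3)."""
    arr = _check_tau2(tau2)
    out = arr / (arr + LOGISTIC_RESIDUAL_VARIANCE)
    return float(out) if np.ndim(tau2) == 0 else out


def median_odds_ratio(tau2):
    """Median odds ratio, exp(sqrt(2 tau^2) * PHI^-1(0.75)); always >= 1."""
    arr = _check_tau2(tau2)
    out = np.exp(np.sqrt(2.0 * arr) * norm.ppf(0.75))
    return float(out) if np.ndim(tau2) == 0 else out


def pcv(tau2_ref: float, tau2_model: float) -> float:
    """Proportional change in variance vs a reference model, signed percent.

    Negative = variance explained relative to the reference; positive =
    variance inflated (possible when compositional adjustment uncovers
    between-area heterogeneity).
    """
    if tau2_ref <= 0:
        raise ValueError("reference tau2 must be > 0")
    _check_tau2(tau2_model)
    return 100.0 * (tau2_model - tau2_ref) / tau2_ref


def access_explained(tau2_m4: float, tau2_m5: float) -> float:
    """Area variance change attributable to the access term alone.

    The signed percent change from the covariate-adjusted model (M4) to the
    model adding access (M5); negative = access explains additional
    between-area variance beyond the other covariates.
    """
    if tau2_m4 <= 0:
        raise ValueError("tau2 of the adjusted model must be > 0")
    _check_tau2(tau2_m5)
    return 100.0 * (tau2_m5 - tau2_m4) / tau2_m4


@dataclass
class VarianceLadder:
    """Per-model tau^2 / log-likelihood / AIC across a nested model ladder.

    Keys are model names in fitting order; the first entry is the reference
    (null) model for PCV.
    """

    tau2_by_model: dict[str, float]
    loglik_by_model: dict[str, float] = field(default_factory=dict)
    aic_by_model: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tau2_by_model:
            raise ValueError("ladder must contain at least the null model")
        for name, t in self.tau2_by_model.items():
            if t < 0:
                raise ValueError(f"tau2 for {name} must be >= 0")


def ladder_summary(ladder: VarianceLadder) -> pd.DataFrame:
    """Model-comparison table: AIC, tau^2, ICC, MOR and PCV per model.

    Values are unrounded machine numbers; display rounding (ICC % to 1 d.p.,
    MOR to 2-3 d.p.) is applied by the pipeline writers.
    """
    names = list(ladder.tau2_by_model)
    ref_name = names[0]
    ref = ladder.tau2_by_model[ref_name]
    rows = []
    for name in names:
        t = ladder.tau2_by_model[name]
        rows.append({
            "model": name,
            "aic": ladder.aic_by_model.get(name, np.nan),
            "loglik": ladder.loglik_by_model.get(name, np.nan),
            "tau2": t,
            "icc_pct": 100.0 * icc_latent(t),
            "mor": median_odds_ratio(t),
            "pcv_pct": np.nan if (name == ref_name or ref <= 0) else pcv(ref, t),
        })
    return pd.DataFrame(rows)
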