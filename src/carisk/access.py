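"""Two-step floating catchment area (2SFCA) access index.

Step 1 computes, for every provider site *j*, the supply-to-demand ratio

    R_j = S_j / sum_i p_i

over the areas whose centroids lie within the buffer radius d0 of the site
(S_j = GP head count, p_i = adult population). Step 2 sums, for every area
*i*, the ratios of all sites reachable within the same d0:

    A_i = sum_j R_j

A_i is practitioners per capita; a per-1000 reporting scale is provided but
never feeds the models (covariates are standardized anyway). Distances are
straight-line Euclidean on planar km coordinates and the catchment boundary
is inclusive (d <= d0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "AccessConfig",
    "catchment_members",
    "provider_ratios",
    "access_index",
    "coverage_sensitivity",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccessConfig:
    """Buffer radius (km) and reporting scale of the access computation."""

    buffer_km: float = 30.0
    per_capita_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.buffer_km <= 0:
            raise ValueError("buffer_km must be > 0")
        if self.per_capita_scale <= 0:
            raise ValueError("per_capita_scale must be > 0")


def _coords(df: pd.DataFrame) -> np.ndarray:
    xy = df[["x_km", "y_km"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("coordinates must be finite")
    return xy


def catchment_members(centres, points, d0: float) -> list[np.ndarray]:
    """Indices of ``points`` within Euclidean distance d0 of each centre.

    Boundary inclusive: a point at exactly d0 is a member. Accepts (n, 2)
    arrays or DataFrames with x_km/y_km columns.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    c = _coords(centres) if isinstance(centres, pd.DataFrame) else np.asarray(centres, float)
    p = _coords(points) if isinstance(points, pd.DataFrame) else np.asarray(points, float)
    c = c.reshape(-1, 2)
    p = p.reshape(-1, 2)
    if not (np.isfinite(c).all() and np.isfinite(p).all()):
        raise ValueError("coordinates must be finite")
    if len(c) == 0 or len(p) == 0:
        return [np.empty(0, dtype=int) for _ in range(len(c))]
    d = cdist(c, p)
    return [np.flatnonzero(row <= d0) for row in d]


def provider_ratios(
    providers: pd.DataFrame, areas: pd.DataFrame, config: AccessConfig = AccessConfig()
) -> pd.DataFrame:
    """Step 1: supply-to-demand ratio R_j per provider site.

    Sites whose catchment holds no areas, or only zero population, get a NaN
    ratio (undefined) and are excluded from step 2; a warning reports them.
    The buffer used is recorded on the result for the step-2 consistency
    check.
    """
    out = providers.copy()
    members = catchment_members(providers, areas, config.buffer_km)
    pop = areas["adult_pop"].to_numpy(float)
    gp = providers["gp_count"].to_numpy(float)
    ratio = np.full(len(providers), np.nan)
    for j, idx in enumerate(members):
        demand = pop[idx].sum()
        if demand > 0:
            ratio[j] = gp[j] / demand
    undefined = out.loc[np.isnan(ratio), "site_id"].tolist()
    if undefined:
        log.warning(
            "%d provider site(s) with empty or zero-population catchment "
            "excluded from step 2: %s", len(undefined), undefined,
        )
    out["ratio"] = ratio
    out.attrs["buffer_km"] = config.buffer_km
    return out


def access_index(
    areas: pd.DataFrame, providers: pd.DataFrame, config: AccessConfig = AccessConfig()
) -> pd.DataFrame:
    """Step 2: access index A_i per area.

    Requires ``providers`` to carry ratios computed at the same buffer
    radius (both steps must share one catchment definition). Areas reaching
    no defined-ratio site get A_i = 0.
    """
    step1_buffer = providers.attrs.get("buffer_km")
    if step1_buffer is None:
        raise ValueError("providers have no ratios; run provider_ratios first")
    if step1_buffer != config.buffer_km:
        raise ValueError(
            f"buffer mismatch: ratios computed at d0={step1_buffer} km, "
            f"access requested at d0={config.buffer_km} km"
        )
    out = areas.copy()
    members = catchment_members(areas, providers, config.buffer_km)
    ratio = providers["ratio"].to_numpy(float)
    acc = np.array([np.nansum(ratio[idx]) if len(idx) else 0.0 for idx in members])
    out["access"] = acc
    out["access_per_1000"] = acc * config.per_capita_scale
    return out


def coverage_sensitivity(
    areas: pd.DataFrame, providers: pd.DataFrame, radii=(1.0, 16.0, 30.0)
) -> pd.DataFrame:
    """Count area centroids within each candidate radius of >= 1 provider.

    One row per radius: buffer_km, n_covered, n_total, fraction. Used to
    justify the working buffer choice before committing to one d0.
    """
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    n_total = len(areas)
    rows = []
    if n_total and len(providers):
        d = cdist(_coords(areas), _coords(providers)).min(axis=1)
    else:
        d = np.full(n_total, np.inf)
    for r in radii:
        n_cov = int((d <= r).sum())
        rows.append({
            "buffer_km": r,
            "n_covered": n_cov,
            "n_total": n_total,
            "fraction": n_cov / n_total if n_total else 0.0,
        })
    return pd.DataFrame(rows)
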