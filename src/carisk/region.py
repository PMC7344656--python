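"""Synthetic small-area study regions.

Generates planar study regions with the structure the downstream access and
multilevel analyses assume: small census-style areas (centroid, adult
population, IRSD-style disadvantage score where higher = less disadvantaged),
primary-care provider sites with GP head counts, and person-level pathology
test records nested in areas. Binary higher-risk outcomes are simulated from
a random-intercept logistic model so that every fitting stage can be
exercised against known generating parameters.

Tabular objects are pandas DataFrames with fixed column contracts:

* areas:     area_id, x_km, y_km, adult_pop, irsd (NaN = missing),
             access (NaN until computed by :mod:`carisk.access`)
* providers: site_id, x_km, y_km, gp_count, ratio (NaN until computed)
* records:   record_id, person_id, area_id, sex, age_group, cmrf,
             test_value, test_date, higher_risk

Coordinates are kilometres in an arbitrary projected plane; no geodesy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "AGE_BANDS",
    "CMRFS",
    "RegionConfig",
    "OutcomeModelParams",
    "DEFAULT_OUTCOME_PARAMS",
    "STUDY_WINDOW",
    "generate_areas",
    "generate_providers",
    "generate_persons",
    "simulate_outcomes",
    "compute_standardization",
]

#: Adult age bands; the first is the reference category in all models.
AGE_BANDS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")

#: The seven cardiometabolic risk factor test types.
CMRFS = ("FBSL", "HbA1c", "TC", "HDL", "ACR", "eGFR", "BMI")

#: Default pathology-test study window (inclusive).
STUDY_WINDOW = (date(2012, 1, 1), date(2017, 12, 31))

#: Default age mix of the tested adult cohort over the seven bands.
#: Pathology testing skews older than the resident age pyramid.
DEFAULT_AGE_MIX = (0.15, 0.15, 0.17, 0.17, 0.16, 0.12, 0.08)


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of a synthetic study region.

    Defaults emulate a mixed urban/rural coastal region of ~980 small census
    areas averaging 400 adults (range 200-800), 165 primary-care sites with
    611 GPs in total, and a disadvantage score distributed N(976.7, 98.6^2).
    ``region_extent`` is the (width, height) of the planar frame in km; the
    default 110 x 51 km matches a ~5600 km^2 elongated coastal region.
    """

    n_areas: int = 980
    pop_range: tuple[int, int] = (200, 800)
    region_extent: tuple[float, float] = (110.0, 51.0)
    n_provider_sites: int = 165
    gp_total: int = 611
    irsd_mean: float = 976.7
    irsd_sd: float = 98.6
    irsd_missing_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        lo, hi = self.pop_range
        if lo < 1 or lo > hi:
            raise ValueError("pop_range must satisfy 1 <= min <= max")
        if self.n_provider_sites < 0:
            raise ValueError("n_provider_sites must be >= 0")
        if self.gp_total < self.n_provider_sites:
            raise ValueError("gp_total must be >= n_provider_sites")
        if self.irsd_sd <= 0:
            raise ValueError("irsd_sd must be > 0")
        if not (0.0 <= self.irsd_missing_frac < 1.0):
            raise ValueError("irsd_missing_frac must be in [0, 1)")
        w, h = self.region_extent
        if w <= 0 or h <= 0:
            raise ValueError("region_extent must be positive")


@dataclass(frozen=True)
class OutcomeModelParams:
    """Generating parameters of the person-level risk model.

    The linear predictor for a person in area *a* is::

        eta = intercept + beta_male * [male] + beta_age[band - 1]
              + beta_irsd * z_irsd(a) + beta_access * z_access(a) + u_a

    with ``u_a ~ N(0, tau2)`` drawn once per area, and the outcome
    Bernoulli(expit(eta)). ``beta_age`` holds log-odds for the six non-
    reference age bands (reference 18-29). Continuous area covariates enter
    as per-SD z-scores using area-level standardization constants.
    """

    intercept: float
    beta_male: float = 0.0
    beta_age: tuple[float, ...] = (0.0,) * 6
    beta_irsd: float = 0.0
    beta_access: float = 0.0
    tau2: float = 0.0

    def __post_init__(self) -> None:
        if len(self.beta_age) != 6:
            raise ValueError("beta_age must have exactly 6 entries")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")


def _ln(x: float) -> float:
    return float(np.log(x))


#: Literature-anchored generating parameters per CMRF (fully adjusted model
#: scale: fixed effects are log odds ratios of the adjusted fits, tau2 the
#: residual area variance). Used as pipeline defaults for simulated studies.
DEFAULT_OUTCOME_PARAMS: dict[str, OutcomeModelParams] = {
    "FBSL": OutcomeModelParams(
        intercept=_ln(0.01), beta_male=_ln(1.63),
        beta_age=(_ln(1.65), _ln(3.57), _ln(6.80), _ln(11.05), _ln(13.8), _ln(12.1)),
        beta_irsd=_ln(0.79), beta_access=_ln(0.98), tau2=0.039),
    "HbA1c": OutcomeModelParams(
        intercept=_ln(0.07), beta_male=_ln(1.39),
        beta_age=(_ln(0.81), _ln(1.26), _ln(1.57), _ln(1.64), _ln(1.63), _ln(1.62)),
        beta_irsd=_ln(0.79), beta_access=0.0, tau2=0.047),
    "TC": OutcomeModelParams(
        intercept=_ln(0.20), beta_male=_ln(0.69),
        beta_age=(_ln(2.01), _ln(3.00), _ln(4.07), _ln(2.95), _ln(1.61), _ln(1.14)),
        beta_irsd=_ln(1.06), beta_access=0.0, tau2=0.017),
    "HDL": OutcomeModelParams(
        intercept=_ln(0.06), beta_male=_ln(3.98),
        beta_age=(_ln(1.12), _ln(1.00), _ln(0.88), _ln(0.82), _ln(0.85), _ln(0.91)),
        beta_irsd=_ln(0.82), beta_access=_ln(0.95), tau2=0.029),
    "ACR": OutcomeModelParams(
        intercept=_ln(0.02), beta_male=_ln(1.75),
        beta_age=(_ln(1.00), _ln(0.70), _ln(0.77), _ln(0.96), _ln(1.54), _ln(2.70)),
        beta_irsd=_ln(0.82), beta_access=_ln(0.97), tau2=0.025),
    "eGFR": OutcomeModelParams(
        intercept=-8.0, beta_male=_ln(0.98),
        beta_age=(_ln(1.65), _ln(4.30), _ln(12.28), _ln(41.83), _ln(149.6), _ln(503.0)),
        beta_irsd=_ln(0.90), beta_access=0.0, tau2=0.013),
    "BMI": OutcomeModelParams(
        intercept=_ln(0.25), beta_male=_ln(0.99),
        beta_age=(_ln(1.64), _ln(2.20), _ln(2.44), _ln(2.72), _ln(2.42), _ln(1.45)),
        beta_irsd=_ln(0.82), beta_access=_ln(0.93), tau2=0.062),
}


def generate_areas(config: RegionConfig) -> pd.DataFrame:
    """Generate the area table of a synthetic region.

    Centroids are uniform over the planar frame, adult populations uniform
    integers in ``pop_range``, disadvantage scores N(irsd_mean, irsd_sd^2)
    with a configured fraction missing completely at random. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng([0, config.seed])
    n = config.n_areas
    w, h = config.region_extent
    lo, hi = config.pop_range
    irsd = rng.normal(config.irsd_mean, config.irsd_sd, n)
    if config.irsd_missing_frac > 0:
        irsd[rng.random(n) < config.irsd_missing_frac] = np.nan
    return pd.DataFrame({
        "area_id": [f"A{i:04d}" for i in range(n)],
        "x_km": rng.uniform(0.0, w, n),
        "y_km": rng.uniform(0.0, h, n),
        "adult_pop": rng.integers(lo, hi + 1, n),
        "irsd": irsd,
        "access": np.nan,
    })


def generate_providers(config: RegionConfig, areas: pd.DataFrame) -> pd.DataFrame:
    """Generate provider sites co-located with population.

    Sites are placed near the centroids of areas sampled with probability
    proportional to adult population (provider locations correlate with
    population density), with ~1 km of jitter. Each site receives at least
    one GP; the remaining ``gp_total - n_provider_sites`` practitioners are
    spread multinomially. Deterministic given ``config.seed``.
    """
    if config.n_provider_sites == 0:
        return pd.DataFrame(
            columns=["site_id", "x_km", "y_km", "gp_count", "ratio"]
        ).astype({"x_km": float, "y_km": float, "gp_count": int, "ratio": float})
    if len(areas) == 0:
        raise ValueError("areas must be non-empty when n_provider_sites > 0")
    rng = np.random.default_rng([1, config.seed])
    m = config.n_provider_sites
    pop = areas["adult_pop"].to_numpy(float)
    p = pop / pop.sum()
    host = rng.choice(len(areas), size=m, p=p)
    x = areas["x_km"].to_numpy()[host] + rng.normal(0.0, 1.0, m)
    y = areas["y_km"].to_numpy()[host] + rng.normal(0.0, 1.0, m)
    gp = np.ones(m, dtype=int)
    extra = config.gp_total - m
    if extra > 0:
        gp += rng.multinomial(extra, np.full(m, 1.0 / m))
    return pd.DataFrame({
        "site_id": [f"S{j:03d}" for j in range(m)],
        "x_km": x,
        "y_km": y,
        "gp_count": gp,
        "ratio": np.nan,
    })


def generate_persons(
    areas: pd.DataFrame,
    window: tuple[date, date] = STUDY_WINDOW,
    seed: int = 0,
    sampling_fraction: float = 0.65,
    male_share: float = 0.48,
    age_mix: tuple[float, ...] = DEFAULT_AGE_MIX,
    cmrfs: tuple[str, ...] = CMRFS,
    repeat_rate: float = 0.10,
) -> pd.DataFrame:
    """Generate person-level test records (values and outcomes unset).

    Each area contributes ``round(sampling_fraction * adult_pop)`` tested
    persons; sex and age band are drawn per person, and each person gets one
    record per CMRF with a test date uniform in ``window``. With probability
    ``repeat_rate`` a record gains an additional repeat test (independent
    date), so most-recent-test selection has work to do.
    """
    start, end = window
    if end < start:
        raise ValueError("window end precedes start")
    if len(areas) == 0:
        raise ValueError("areas must be non-empty")
    if not (0.0 < sampling_fraction <= 1.0):
        raise ValueError("sampling_fraction must be in (0, 1]")
    probs = np.asarray(age_mix, float)
    if len(probs) != len(AGE_BANDS) or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("age_mix must be 7 probabilities summing to 1")

    rng = np.random.default_rng([2, seed])
    n_per_area = np.rint(sampling_fraction * areas["adult_pop"].to_numpy(float)).astype(int)
    n_persons = int(n_per_area.sum())
    area_ids = np.repeat(areas["area_id"].to_numpy(), n_per_area)
    persons = pd.DataFrame({
        "person_id": np.arange(n_persons),
        "area_id": area_ids,
        "sex": np.where(rng.random(n_persons) < male_share, "male", "female"),
        "age_group": rng.choice(AGE_BANDS, size=n_persons, p=probs),
    })

    base = persons.loc[persons.index.repeat(len(cmrfs))].reset_index(drop=True)
    base["cmrf"] = np.tile(np.asarray(cmrfs, object), n_persons)
    if repeat_rate > 0:
        repeats = base[rng.random(len(base)) < repeat_rate]
        records = pd.concat([base, repeats], ignore_index=True)
    else:
        records = base
    n_days = (end - start).days + 1
    offsets = rng.integers(0, n_days, len(records))
    records["test_date"] = pd.to_datetime(start) + pd.to_timedelta(offsets, unit="D")
    records["test_value"] = np.nan
    records["higher_risk"] = np.nan
    records.insert(0, "record_id", np.arange(len(records)))
    return records


def compute_standardization(areas: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Area-level (unweighted) mean/SD constants for the continuous covariates.

    Computed over areas, not persons, so every model — and the outcome
    simulation — shares one set of per-SD scalings. Missing scores are
    ignored in the constants.
    """
    out: dict[str, dict[str, float]] = {}
    for col in ("irsd", "access"):
        v = areas[col].dropna().to_numpy(float)
        if v.size == 0:
            raise ValueError(f"no non-missing values to standardize column {col!r}")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        if sd <= 0:
            raise ValueError(f"column {col!r} has zero variance across areas")
        out[col] = {"mean": float(v.mean()), "sd": sd}
    return out


def simulate_outcomes(
    records: pd.DataFrame,
    areas: pd.DataFrame,
    params: OutcomeModelParams | dict[str, OutcomeModelParams],
    seed: int = 0,
    constants: dict[str, dict[str, float]] | None = None,
    on_missing_irsd: str = "error",
    return_effects: bool = False,
):
    """Simulate binary higher-risk outcomes under the random-intercept model.

    One area effect ``u_a ~ N(0, tau2)`` is drawn per area (per CMRF when
    ``params`` is a mapping), and one Bernoulli outcome per distinct
    (person, CMRF) pair — repeat tests of the same person share the outcome.
    Deterministic given ``seed``.

    Parameters
    ----------
    params
        A single :class:`OutcomeModelParams` applied to every CMRF present,
        or a mapping ``cmrf -> params``.
    constants
        Standardization constants as from :func:`compute_standardization`;
        computed from ``areas`` when omitted.
    on_missing_irsd
        ``"error"`` (default) raises listing areas that host persons but lack
        a disadvantage score; ``"drop"`` silently excludes those records.
    return_effects
        Also return the drawn per-area effects as a DataFrame
        (cmrf, area_id, u).
    """
    if constants is None:
        constants = compute_standardization(areas)
    if areas["access"].isna().any():
        raise ValueError("areas must have access set (run the 2SFCA step first)")

    used = areas[areas["area_id"].isin(records["area_id"].unique())]
    missing = used.loc[used["irsd"].isna(), "area_id"].tolist()
    if missing:
        if on_missing_irsd == "error":
            raise ValueError(f"areas with persons but missing irsd: {missing}")
        if on_missing_irsd != "drop":
            raise ValueError("on_missing_irsd must be 'error' or 'drop'")
        records = records[~records["area_id"].isin(missing)]

    area_idx = pd.Index(areas["area_id"])
    z_irsd = (areas["irsd"].to_numpy(float) - constants["irsd"]["mean"]) / constants["irsd"]["sd"]
    z_access = (areas["access"].to_numpy(float) - constants["access"]["mean"]) / constants["access"]["sd"]

    out = records.copy()
    out["higher_risk"] = np.nan
    effects = []
    cmrf_list = list(pd.unique(out["cmrf"]))
    for k, cmrf in enumerate(cmrf_list):
        par = params[cmrf] if isinstance(params, dict) else params
        rng = np.random.default_rng([3, seed, k])
        u = rng.normal(0.0, np.sqrt(par.tau2), len(areas))
        mask = (out["cmrf"] == cmrf).to_numpy()
        sub = out.loc[mask, ["person_id", "area_id", "sex", "age_group"]]
        first = ~sub["person_id"].duplicated()
        uniq = sub[first]
        a = area_idx.get_indexer(uniq["area_id"])
        band = pd.Categorical(uniq["age_group"], categories=AGE_BANDS).codes
        beta_age = np.concatenate([[0.0], par.beta_age])
        eta = (
            par.intercept
            + par.beta_male * (uniq["sex"].to_numpy() == "male")
            + beta_age[band]
            + par.beta_irsd * z_irsd[a]
            + par.beta_access * z_access[a]
            + u[a]
        )
        y = (rng.random(len(uniq)) < expit(eta)).astype(float)
        y_by_person = pd.Series(y, index=uniq["person_id"].to_numpy())
        out.loc[mask, "higher_risk"] = y_by_person.reindex(sub["person_id"]).to_numpy()
        effects.append(pd.DataFrame({"cmrf": cmrf, "area_id": areas["area_id"], "u": u}))

    if return_effects:
        return out, pd.concat(effects, ignore_index=True)
    return out


def params_for_prevalence(prevalence: float, tau2: float = 0.0) -> OutcomeModelParams:
    """Null-covariate generating parameters with a target overall prevalence."""
    return OutcomeModelParams(intercept=float(logit(prevalence)), tau2=tau2)
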