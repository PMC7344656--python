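"""End-to-end study orchestration.

Generates or loads a region, computes 2SFCA access and its buffer
sensitivity, builds per-CMRF analysis cohorts, fits the nested
random-intercept model ladder M1-M5 for each risk factor, and derives the
contextual-effect summary. Every run writes a manifest (seed, config echo,
standardization constants, versions) sufficient to reproduce the outputs
byte for byte.

The model ladder:

* M1 null (intercept only)
* M2 = M1 + access
* M3 = M1 + sex + age
* M4 = M3 + disadvantage score
* M5 = M4 + access

Likelihood-ratio tests follow the available nesting arrows (M2 is not
nested in M3): M1->M2, M1->M3, M3->M4, M4->M5.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .access import AccessConfig, access_index, coverage_sensitivity, provider_ratios
from .cohort import classify_risk, exclude_incomplete, risk_summary, select_most_recent
from .contextual import VarianceLadder, access_explained, ladder_summary
from .glmm import GlmmFit, ModelSpec, fit_ml, lr_test, odds_ratios
from .region import (
    CMRFS,
    DEFAULT_OUTCOME_PARAMS,
    STUDY_WINDOW,
    OutcomeModelParams,
    RegionConfig,
    compute_standardization,
    generate_areas,
    generate_persons,
    generate_providers,
    simulate_outcomes,
)

__all__ = ["MODEL_TERMS", "LadderRun", "RunConfig", "run_ladder", "run_study"]

log = logging.getLogger(__name__)

#: Fixed-effect terms of the nested ladder, in fitting order.
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("intercept",),
    "M2": ("intercept", "access_z"),
    "M3": ("intercept", "sex", "age_group"),
    "M4": ("intercept", "sex", "age_group", "irsd_z"),
    "M5": ("intercept", "sex", "age_group", "irsd_z", "access_z"),
}

#: Successive-nesting LRT comparisons (nested, full).
LRT_PAIRS = (("M1", "M2"), ("M1", "M3"), ("M3", "M4"), ("M4", "M5"))


def _columns_for(terms: tuple[str, ...]) -> list[str]:
    from .region import AGE_BANDS
    cols = []
    for term in ("intercept", "sex", "age_group", "irsd_z", "access_z"):
        if term not in terms:
            continue
        if term == "intercept":
            cols.append("intercept")
        elif term == "sex":
            cols.append("male")
        elif term == "age_group":
            cols += [f"age_{b}" for b in AGE_BANDS[1:]]
        else:
            cols.append(term)
    return cols


@dataclass
class LadderRun:
    """All fitted artifacts of one CMRF's nested model ladder."""

    cmrf: str
    fits: dict[str, GlmmFit]
    or_tables: dict[str, pd.DataFrame]
    ladder: VarianceLadder
    summary: pd.DataFrame
    lrts: pd.DataFrame
    access_explained_pct: float | None
    failures: dict[str, str] = field(default_factory=dict)


def run_ladder(
    records: pd.DataFrame,
    areas: pd.DataFrame,
    quadrature_order: int = 15,
    models: tuple[str, ...] = tuple(MODEL_TERMS),
    constants: dict | None = None,
    compute_se: bool = True,
    outcome_col: str = "higher_risk",
) -> LadderRun:
    """Fit the nested model ladder for one CMRF's analysis records.

    ``records`` holds one dichotomized row per person (columns person_id,
    area_id, sex, age_group, and the outcome); the disadvantage score and
    access index are merged in from ``areas``. All models share one set of
    area-level standardization constants.
    """
    cmrf = str(records["cmrf"].iloc[0]) if "cmrf" in records.columns else ""
    if constants is None:
        constants = compute_standardization(areas)
    need = [c for c in ("irsd", "access") if c not in records.columns]
    df = records
    if need:
        df = records.merge(areas[["area_id", *need]], on="area_id", how="left")

    fits: dict[str, GlmmFit] = {}
    failures: dict[str, str] = {}
    for name in models:
        terms = MODEL_TERMS[name]
        spec = ModelSpec(outcome=outcome_col, fixed_terms=terms,
                         quadrature_order=quadrature_order, name=name)
        start = None
        prev = [f for f in fits.values()]
        if prev:
            donor = prev[-1]
            cols = _columns_for(terms)
            beta0 = np.array([
                donor.beta[donor.columns.index(c)] if c in donor.columns else 0.0
                for c in cols
            ])
            sigma0 = max(np.sqrt(donor.tau2), 0.05)
            start = (beta0, float(np.log(sigma0)))
        t0 = time.perf_counter()
        try:
            fit = fit_ml(spec, df, constants, start=start, compute_se=compute_se)
        except Exception as exc:  # keep the run going; record the failure
            failures[name] = str(exc)
            log.warning("ladder %s model %s failed: %s", cmrf, name, exc)
            continue
        fits[name] = fit
        log.info("ladder %s %s: loglik=%.2f tau2=%.4g (%.1fs)",
                 cmrf, name, fit.loglik, fit.tau2, time.perf_counter() - t0)

    ladder = VarianceLadder(
        tau2_by_model={m: f.tau2 for m, f in fits.items()},
        loglik_by_model={m: f.loglik for m, f in fits.items()},
        aic_by_model={m: f.aic for m, f in fits.items()},
    )
    summary = ladder_summary(ladder)

    lrt_rows = []
    for nested, full in LRT_PAIRS:
        if nested not in fits or full not in fits:
            continue
        assert set(MODEL_TERMS[nested]) < set(MODEL_TERMS[full]), "nesting violated"
        stat, dof, p = lr_test(fits[nested], fits[full])
        lrt_rows.append({"nested": nested, "full": full,
                         "statistic": stat, "df": dof, "p_value": p})
    lrts = pd.DataFrame(lrt_rows, columns=["nested", "full", "statistic", "df", "p_value"])

    acc_expl = None
    if "M4" in fits and "M5" in fits and fits["M4"].tau2 > 0:
        acc_expl = access_explained(fits["M4"].tau2, fits["M5"].tau2)

    return LadderRun(
        cmrf=cmrf, fits=fits,
        or_tables={m: odds_ratios(f) for m, f in fits.items()},
        ladder=ladder, summary=summary, lrts=lrts,
        access_explained_pct=acc_expl, failures=failures,
    )


@dataclass
class RunConfig:
    """Configuration of a full study run (simulate or load mode)."""

    mode: str = "simulate"
    # load mode inputs
    areas_path: str | None = None
    providers_path: str | None = None
    persons_path: str | None = None
    # simulate mode inputs
    region: RegionConfig = field(default_factory=RegionConfig)
    outcome_params: dict[str, OutcomeModelParams] | None = None
    sampling_fraction: float = 0.65
    male_share: float = 0.48
    repeat_rate: float = 0.10
    # shared
    access: AccessConfig = field(default_factory=AccessConfig)
    sensitivity_radii: tuple[float, ...] = (1.0, 16.0, 30.0)
    cmrfs: tuple[str, ...] = CMRFS
    window: tuple[date, date] = STUDY_WINDOW
    quadrature_order: int = 15
    seed: int = 0
    outdir: str = "carisk_out"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if not self.cmrfs:
            raise ValueError("cmrf list must be non-empty")
        unknown = set(self.cmrfs) - set(CMRFS)
        if unknown:
            raise ValueError(f"unknown CMRFs: {sorted(unknown)}")
        if self.mode == "load":
            missing = [n for n, p in [("areas_path", self.areas_path),
                                      ("providers_path", self.providers_path),
                                      ("persons_path", self.persons_path)] if p is None]
            if missing:
                raise ValueError(f"load mode requires paths: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "region" in kw and isinstance(kw["region"], dict):
            region = dict(kw["region"])
            for tup_key in ("pop_range", "region_extent"):
                if tup_key in region:
                    region[tup_key] = tuple(region[tup_key])
            kw["region"] = RegionConfig(**region)
        if "access" in kw and isinstance(kw["access"], dict):
            kw["access"] = AccessConfig(**kw["access"])
        if "outcome_params" in kw and isinstance(kw["outcome_params"], dict):
            kw["outcome_params"] = {
                c: (OutcomeModelParams(**{**p, "beta_age": tuple(p.get("beta_age", (0.0,) * 6))})
                    if isinstance(p, dict) else p)
                for c, p in kw["outcome_params"].items()
            }
        for tup_key in ("cmrfs", "sensitivity_radii"):
            if tup_key in kw:
                kw[tup_key] = tuple(kw[tup_key])
        if "window" in kw:
            kw["window"] = tuple(
                date.fromisoformat(d) if isinstance(d, str) else d for d in kw["window"]
            )
        return cls(**kw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = [w.isoformat() for w in self.window]
        # the output directory is where the manifest itself lives; echoing it
        # would break byte-identity of reruns into different directories
        d.pop("outdir")
        return d


def _read_table(path: str) -> pd.DataFrame:
    p = str(path)
    if p.endswith((".geojson", ".json")):
        return io.read_points_geojson(p)
    return io.read_areas_csv(p) if "area" in Path(p).stem else io.read_providers_csv(p)


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle.

    Returns a dict with the in-memory artifacts (areas, providers, records,
    cohorts, risk summary, ladder runs, manifest) alongside the paths
    written under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    if config.mode == "simulate":
        areas = generate_areas(config.region)
        providers = generate_providers(config.region, areas)
    else:
        areas = _read_table(config.areas_path)
        providers = _read_table(config.providers_path)
        if "ratio" not in providers.columns:
            providers["ratio"] = np.nan

    providers = provider_ratios(providers, areas, config.access)
    areas = access_index(areas, providers, config.access)
    coverage = coverage_sensitivity(areas, providers, config.sensitivity_radii)
    log.info("access stage done (%.1fs)", time.perf_counter() - t_start)

    constants = compute_standardization(areas)

    if config.mode == "simulate":
        params = {c: (config.outcome_params or DEFAULT_OUTCOME_PARAMS)[c]
                  for c in config.cmrfs}
        records = generate_persons(
            areas, window=config.window, seed=config.seed,
            sampling_fraction=config.sampling_fraction,
            male_share=config.male_share, cmrfs=config.cmrfs,
            repeat_rate=config.repeat_rate,
        )
        records = simulate_outcomes(records, areas, params, seed=config.seed,
                                    constants=constants, on_missing_irsd="drop")
    else:
        records = io.read_records_csv(config.persons_path)
        records = records[records["cmrf"].isin(config.cmrfs)]
    log.info("%d test records in hand (%.1fs)", len(records),
             time.perf_counter() - t_start)

    latest = select_most_recent(records, config.window)
    needs_class = latest["higher_risk"].isna() & latest["test_value"].notna()
    if needs_class.any():
        sub = latest[needs_class]
        flags = np.concatenate([
            classify_risk(c, g["test_value"].to_numpy()).astype(float)
            for c, g in sub.groupby("cmrf", sort=False)
        ])
        order = np.concatenate([g.index.to_numpy()
                                for _, g in sub.groupby("cmrf", sort=False)])
        latest.loc[order, "higher_risk"] = flags
    cohorts, exclusion_log = exclude_incomplete(latest, areas)
    summary = risk_summary(cohorts)

    ladders: dict[str, LadderRun] = {}
    for cmrf in config.cmrfs:
        sub = cohorts[cohorts["cmrf"] == cmrf]
        if sub.empty:
            log.warning("no records for %s; skipping ladder", cmrf)
            continue
        ladders[cmrf] = run_ladder(sub, areas,
                                   quadrature_order=config.quadrature_order,
                                   constants=constants)
        log.info("ladder %s done (%.1fs)", cmrf, time.perf_counter() - t_start)

    # ---- write the bundle -------------------------------------------------
    io.write_table_csv(areas.drop(columns=["access_per_1000"], errors="ignore"),
                       out / "areas.csv")
    io.write_points_geojson(areas, out / "areas.geojson")
    io.write_table_csv(providers, out / "providers.csv")
    io.write_points_geojson(providers, out / "providers.geojson")
    io.write_records_csv(records, out / "persons.csv")
    acc = areas[["area_id", "access"]].copy()
    acc.columns = ["area_id", "access_raw"]
    acc["access_per_1000"] = acc["access_raw"] * config.access.per_capita_scale
    io.write_table_csv(acc, out / "access.csv")
    io.write_table_csv(coverage, out / "coverage.csv")
    io.write_table_csv(summary, out / "risk_summary.csv")
    for cmrf, run in ladders.items():
        cohort_cols = ["person_id", "area_id", "sex", "age_group", "higher_risk"]
        io.write_table_csv(
            cohorts.loc[cohorts["cmrf"] == cmrf, cohort_cols],
            out / f"cohort_{cmrf}.csv")
        fit_doc = {
            "cmrf": cmrf,
            "fits": {m: f.to_dict() for m, f in run.fits.items()},
            "lrts": run.lrts.to_dict(orient="records"),
            "access_explained_pct": run.access_explained_pct,
            "failures": run.failures,
        }
        (out / f"fits_{cmrf}.json").write_text(
            json.dumps(fit_doc, indent=1, sort_keys=True) + "\n")
        display = run.summary.copy()
        display["icc_pct_1dp"] = display["icc_pct"].round(1)
        display["mor_3dp"] = display["mor"].round(3)
        display["pcv_2dp"] = display["pcv_pct"].round(2)
        io.write_table_csv(display, out / f"ladder_{cmrf}.csv")
        for m, tab in run.or_tables.items():
            disp = tab.copy()
            for c in ("or", "ci_low", "ci_high"):
                disp[f"{c}_2dp"] = disp[c].round(2)
            io.write_table_csv(disp, out / f"or_{cmrf}_{m}.csv")

    manifest = {
        "package": "carisk",
        "seed": config.seed,
        "config": config.echo(),
        "standardization": constants,
        "n_records": int(len(records)),
        "n_cohort_rows": int(len(cohorts)),
        "exclusions": exclusion_log,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    return {
        "areas": areas, "providers": providers, "coverage": coverage,
        "records": records, "cohorts": cohorts, "risk_summary": summary,
        "ladders": ladders, "manifest": manifest, "outdir": out,
    }


def _versions() -> dict[str, str]:
    from importlib.metadata import version

    from . import __version__
    out = {"carisk": __version__}
    for pkg in ("numpy", "scipy", "pandas", "statsmodels", "click"):
        out[pkg] = version(pkg)
    return out
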