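"""Random-intercept logistic regression by maximum likelihood.

Two-level model: persons nested in small areas, a single Gaussian random
intercept per area with variance tau^2 = sigma^2, and a logit link. The
marginal log-likelihood

    l(beta, sigma) = sum_a log INT prod_{i in a} Bern(y_i | expit(x_i' beta + u))
                               N(u; 0, sigma^2) du

is evaluated by adaptive Gauss-Hermite quadrature centred at each area's
conditional mode (found by a vectorized 1-D Newton iteration on the concave
integrand) and maximized over (beta, log sigma) by L-BFGS-B. At sigma = 0
the model collapses to ordinary logistic regression and the likelihood is
evaluated exactly by that formula.

Standard errors come from a finite-difference Hessian at the optimum; Wald
intervals and p-values accompany the exponentiated coefficients, which are
per-SD odds ratios for standardized continuous covariates by construction
of the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm

from .region import AGE_BANDS

__all__ = [
    "TERM_ORDER",
    "ModelSpec",
    "DesignMatrix",
    "GlmmFit",
    "build_design",
    "marginal_loglik",
    "fit_ml",
    "odds_ratios",
    "lr_test",
]

#: Canonical ordering of fixed-effect terms in every design.
TERM_ORDER = ("intercept", "sex", "age_group", "irsd_z", "access_z")

_SIGMA_FLOOR = 1e-6  # lower optimizer bound on sigma; below ~1e-10 exact sigma=0 formula
_BOUNDARY_SIGMA = 1e-4  # fits at or under this report tau2 = 0 with a boundary flag


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed effects enter the model for a given outcome.

    ``fixed_terms`` is an ordered subset of :data:`TERM_ORDER` and must
    include the intercept; ``quadrature_order`` is an odd node count for the
    adaptive Gauss-Hermite rule.
    """

    outcome: str
    fixed_terms: tuple[str, ...] = ("intercept",)
    grouping: str = "area_id"
    quadrature_order: int = 15
    name: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.fixed_terms) - set(TERM_ORDER)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")
        if "intercept" not in self.fixed_terms:
            raise ValueError("fixed_terms must include the intercept")
        q = self.quadrature_order
        if q < 1 or q % 2 == 0:
            raise ValueError("quadrature_order must be an odd count >= 1")


@dataclass
class DesignMatrix:
    """Response, design columns and group structure, rows sorted by group."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    group_idx: np.ndarray      # per-row group code, non-decreasing
    group_starts: np.ndarray   # reduceat boundaries
    group_labels: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    constants: dict[str, dict[str, float]] | None = None,
) -> DesignMatrix:
    """Build the sorted design matrix for one model.

    Reference coding: female and 18-29 carry no column. Continuous terms are
    transformed to (x - mean)/SD with the supplied standardization constants
    (shared across a model ladder so per-SD odds ratios are comparable).
    """
    df = records.sort_values(spec.grouping, kind="mergesort")
    cols: list[str] = []
    parts: list[np.ndarray] = []
    for term in TERM_ORDER:
        if term not in spec.fixed_terms:
            continue
        if term == "intercept":
            cols.append("intercept")
            parts.append(np.ones(len(df)))
        elif term == "sex":
            cols.append("male")
            parts.append((df["sex"].to_numpy() == "male").astype(float))
        elif term == "age_group":
            codes = pd.Categorical(df["age_group"], categories=AGE_BANDS).codes
            if (codes < 0).any():
                bad = sorted(set(df["age_group"][codes < 0]))
                raise ValueError(f"unseen age-band labels: {bad}")
            for b, band in enumerate(AGE_BANDS[1:], start=1):
                cols.append(f"age_{band}")
                parts.append((codes == b).astype(float))
        else:
            src = {"irsd_z": "irsd", "access_z": "access"}[term]
            if constants is None or src not in constants:
                raise ValueError(f"standardization constants required for {term}")
            mean, sd = constants[src]["mean"], constants[src]["sd"]
            if sd <= 0:
                raise ValueError(f"SD for {src} must be > 0")
            cols.append(term)
            parts.append((df[src].to_numpy(float) - mean) / sd)
    X = np.column_stack(parts)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    y = df[spec.outcome].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1")
    labels, gidx = np.unique(df[spec.grouping].to_numpy(), return_inverse=True)
    # rows are sorted by group, so gidx is non-decreasing
    starts = np.flatnonzero(np.diff(gidx, prepend=-1))
    return DesignMatrix(y=y, X=X, columns=cols, group_idx=gidx,
                        group_starts=starts, group_labels=labels)


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _find_modes(eta, y, gidx, starts, inv_s2, u0):
    """Newton iteration for the per-area conditional modes (concave in u)."""
    u = u0.copy()
    for _ in range(100):
        p = expit(eta + u[gidx])
        g = np.add.reduceat(y - p, starts) - u * inv_s2
        W = np.add.reduceat(p * (1.0 - p), starts) + inv_s2
        step = np.clip(g / W, -4.0, 4.0)
        u += step
        if np.max(np.abs(step)) < 1e-11:
            break
    p = expit(eta + u[gidx])
    curv = np.add.reduceat(p * (1.0 - p), starts) + inv_s2
    return u, curv


_hermgauss_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh(order: int):
    if order not in _hermgauss_cache:
        _hermgauss_cache[order] = hermgauss(order)
    return _hermgauss_cache[order]


def _marginal_loglik_u(beta, sigma, design, order, u0):
    """Log-likelihood plus the conditional modes used (for warm starts)."""
    d = design
    eta = d.X @ beta
    if sigma < 1e-10:
        return _logistic_loglik(eta, d.y), np.zeros(d.n_groups)
    inv_s2 = 1.0 / (sigma * sigma)
    u, curv = _find_modes(eta, d.y, d.group_idx, d.group_starts, inv_s2, u0)
    t, w = _gh(order)
    h = np.sqrt(2.0 / curv)
    log_norm_const = -np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    A = np.empty((order, d.n_groups))
    for k in range(order):
        uk = u + h * t[k]
        z = eta + uk[d.group_idx]
        ll_rows = d.y * z - np.logaddexp(0.0, z)
        A[k] = (
            np.log(w[k]) + t[k] * t[k]
            + np.add.reduceat(ll_rows, d.group_starts)
            - 0.5 * uk * uk * inv_s2 + log_norm_const
        )
    ll = float(np.sum(np.log(h) + logsumexp(A, axis=0)))
    return ll, u


def marginal_loglik(
    beta: np.ndarray, log_sigma: float, design: DesignMatrix, order: int = 15
) -> float:
    """Marginal log-likelihood at (beta, log sigma) by adaptive GH quadrature.

    ``log_sigma = -inf`` is the exact sigma = 0 boundary and evaluates the
    ordinary logistic log-likelihood; any other non-finite parameter raises.
    """
    beta = np.asarray(beta, float)
    if not np.isfinite(beta).all():
        raise ValueError("non-finite fixed-effect parameters")
    if np.isnan(log_sigma) or log_sigma == np.inf:
        raise ValueError("non-finite log_sigma")
    sigma = 0.0 if log_sigma == -np.inf else float(np.exp(log_sigma))
    ll, _ = _marginal_loglik_u(beta, sigma, design, order, np.zeros(design.n_groups))
    return ll


@dataclass
class GlmmFit:
    """Maximum-likelihood fit of one random-intercept logistic model."""

    spec: ModelSpec
    columns: list[str]
    beta: np.ndarray
    se: np.ndarray
    tau2: float
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    n_params: int
    converged: bool
    boundary: bool = False
    message: str = ""
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name or "+".join(self.spec.fixed_terms),
            "outcome": self.spec.outcome,
            "fixed_terms": list(self.spec.fixed_terms),
            "columns": list(self.columns),
            "beta": [float(b) for b in self.beta],
            "se": [None if np.isnan(s) else float(s) for s in self.se],
            "tau2": float(self.tau2),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "message": self.message,
        }


def _fd_hessian(f, x, rel_step=1e-4):
    """Central finite-difference Hessian of scalar f at x."""
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f(x) + f(x - ei)) / (h[i] * h[i])
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_ml(
    spec: ModelSpec,
    records: pd.DataFrame,
    constants: dict[str, dict[str, float]] | None = None,
    start: tuple[np.ndarray, float] | None = None,
    compute_se: bool = True,
) -> GlmmFit:
    """Maximize the marginal likelihood over (beta, log sigma).

    Starts from the ordinary logistic fit (or a caller-supplied warm start)
    with a small positive sigma. Fits driven to the sigma -> 0 boundary are
    reported with tau2 = 0 and ``boundary=True``; their SEs come from the
    ordinary logistic information. Non-convergence is reported on the fit,
    not raised.
    """
    design = build_design(records, spec, constants)
    if design.n_groups < 2:
        raise ValueError("need >= 2 areas to estimate a random intercept")
    if design.y.min() == design.y.max():
        raise ValueError(f"outcome {spec.outcome!r} has a single class")

    p = design.X.shape[1]
    if start is not None:
        beta0, log_sigma0 = np.asarray(start[0], float), float(start[1])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                glm = sm.GLM(design.y, design.X, family=sm.families.Binomial())
                beta0 = np.asarray(glm.fit().params, float)
            except Exception:  # separation etc.: fall back to a flat start
                beta0 = np.zeros(p)
        log_sigma0 = np.log(0.2)

    order = spec.quadrature_order
    ucache = {"u": np.zeros(design.n_groups)}

    def nll(theta: np.ndarray) -> float:
        sigma = float(np.exp(theta[-1]))
        ll, u = _marginal_loglik_u(theta[:p], sigma, design, order, ucache["u"])
        ucache["u"] = u
        return -ll

    theta0 = np.concatenate([beta0, [log_sigma0]])
    bounds = [(None, None)] * p + [(np.log(_SIGMA_FLOOR), np.log(20.0))]
    res = minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-6,
                 "maxfun": 20000},
    )
    theta = res.x
    beta = theta[:p]
    sigma = float(np.exp(theta[-1]))
    loglik = -float(res.fun)
    boundary = sigma <= _BOUNDARY_SIGMA
    tau2 = 0.0 if boundary else sigma * sigma
    n_params = p + 1
    aic = -2.0 * loglik + 2.0 * n_params

    se = np.full(p, np.nan)
    if compute_se:
        if boundary:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    logit_fit = sm.Logit(design.y, design.X).fit(disp=0)
                    se = np.asarray(logit_fit.bse, float)
                except Exception:
                    pass
        else:
            try:
                H = _fd_hessian(nll, theta)
                cov = np.linalg.inv(H)
                diag = np.diag(cov)[:p]
                se = np.where(diag > 0, np.sqrt(np.maximum(diag, 0.0)), np.nan)
            except np.linalg.LinAlgError:
                pass

    return GlmmFit(
        spec=spec, columns=design.columns, beta=beta, se=se, tau2=tau2,
        loglik=loglik, aic=aic, n_obs=design.n_obs, n_groups=design.n_groups,
        n_params=n_params, converged=bool(res.success), boundary=boundary,
        message=str(res.message), n_iter=int(res.nit),
    )


def odds_ratios(fit: GlmmFit) -> pd.DataFrame:
    """Exponentiated coefficients with 95% Wald intervals and p-values.

    Continuous covariates were standardized in the design, so their rows are
    odds ratios per SD change.
    """
    z = norm.ppf(0.975)
    beta, se = fit.beta, fit.se
    wald = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    return pd.DataFrame({
        "term": fit.columns,
        "beta": beta,
        "se": se,
        "or": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "p_value": 2.0 * norm.sf(np.abs(wald)),
    })


def lr_test(fit_nested: GlmmFit, fit_full: GlmmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p).

    Requires the nested model's fixed terms to be a subset of the full
    model's and both fits to use the same observations.
    """
    nested_terms = set(fit_nested.spec.fixed_terms)
    full_terms = set(fit_full.spec.fixed_terms)
    if not nested_terms <= full_terms:
        raise ValueError(
            f"models are not nested: {sorted(nested_terms)} vs {sorted(full_terms)}"
        )
    if fit_nested.n_obs != fit_full.n_obs:
        raise ValueError("fits use different numbers of observations")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_nested.loglik))
    df = fit_full.n_params - fit_nested.n_params
    if df == 0:
        p = 1.0 if stat < 1e-8 else 0.0
    else:
        p = float(chi2.sf(stat, df))
    return stat, df, p
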