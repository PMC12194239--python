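"""Count models for sea-urchin bycatch per lobster-trap haul.

The response is the number of urchins found in a trap haul; predictors are
the categorical factors year (2015-2022), fishing-season month
(October-May), zone (RC_A..RC_F), bathymetric depth stratum and lobster
size class (large / small, split at 107.5 mm carapace length).  Four
likelihood families are available -- Poisson, zero-inflated Poisson,
negative binomial (NB2) and zero-inflated negative binomial -- fitted by
maximum likelihood with analytic gradients, and compared by AIC over the
simple (m1-m5) and cumulative (M1-M5) predictor ladders.

Parameterization: the count mean is lambda_i = exp(X_i beta) with treatment
(reference-level) coding; the NB2 variance is lambda + lambda^2/phi (phi >
0, larger = closer to Poisson); zero inflation is a constant mixing
probability pi of a structural zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .errors import DataError

FAMILIES = ("poisson", "zip", "nb", "zinb")

#: declared level sets, first level = reference
LEVELS = {
    "year": ["2015", "2016", "2017", "2018", "2019", "2020", "2021", "2022"],
    "month": ["October", "November", "December", "January",
              "February", "March", "April", "May"],
    "zone": ["RC_A", "RC_B", "RC_C", "RC_D", "RC_E", "RC_F"],
    "depth": ["0-50", "50-100", "100-150", "150-200"],
    "size": ["large", "small"],
}

#: CSV column name per predictor
COLUMNS = {
    "year": "year",
    "month": "month",
    "zone": "zone",
    "depth": "depth_stratum",
    "size": "lobster_size",
}

PREDICTOR_ORDER = ("year", "month", "zone", "depth", "size")


@dataclass
class TrapHaulTable:
    """One record per trap haul: five categorical predictors + urchin count."""

    data: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        required = list(COLUMNS.values()) + ["urchin_count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataError(f"trap-haul table is missing columns {missing}")
        y = df["urchin_count"]
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise DataError("urchin_count must be non-negative integers")
        for pred, col in COLUMNS.items():
            bad = set(df[col].astype(str)) - set(LEVELS[pred])
            if bad:
                raise DataError(f"column {col!r} has unknown levels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def counts(self) -> np.ndarray:
        return self.data["urchin_count"].to_numpy(dtype=np.int64)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrapHaulTable":
        return cls(pd.read_csv(path, dtype={c: str for c in COLUMNS.values()}))


def design_matrix(table: TrapHaulTable, predictors) -> tuple[np.ndarray, list]:
    """Treatment-coded design matrix with intercept.

    The reference level of each factor is the first of its declared range
    (2015, October, RC_A, 0-50 m, large); column order follows the declared
    predictor and level order, so it is deterministic.
    """
    if len(table) == 0:
        raise DataError("empty table")
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for pred in predictors:
        if pred not in LEVELS:
            raise DataError(f"unknown predictor {pred!r}")
        values = table.data[COLUMNS[pred]].astype(str).to_numpy()
        for level in LEVELS[pred][1:]:
            cols.append((values == level).astype(float))
            names.append(f"{pred}[{level}]")
    return np.column_stack(cols), names


# -- log-likelihoods and analytic gradients ------------------------------


def _nb_logpmf(y, mu, phi):
    """NB2 log-pmf: variance mu + mu^2/phi."""
    return (
        gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )


def zinb_loglik(y, X, beta, phi: float, pi: float) -> float:
    """Zero-inflated NB2 log-likelihood with constant zero-inflation.

    Zeros arise either structurally (probability ``pi``) or from the NB
    count process; positive counts only from the NB process:

        y_i = 0:  log[ pi + (1 - pi) NB(0; lambda_i, phi) ]
        y_i > 0:  log[ (1 - pi) NB(y_i; lambda_i, phi) ]

    with lambda_i = exp(X_i beta).
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise DataError("counts must be non-negative integers")
    if not phi > 0:
        raise ValueError("phi must be positive")
    if not (0.0 <= pi < 1.0):
        raise ValueError("pi must lie in [0, 1)")
    mu = np.exp(np.asarray(X) @ np.asarray(beta))
    ll = _nb_logpmf(y, mu, phi)
    zero = y == 0
    if pi > 0:
        ll = np.where(
            zero,
            np.logaddexp(np.log(pi), np.log1p(-pi) + ll),
            np.log1p(-pi) + ll,
        )
    return float(ll.sum())


def _nll_and_grad(theta, y, X, family):
    """Negative log-likelihood and gradient in the packed parameterization
    theta = [beta, log phi (NB families), logit pi (ZI families)]."""
    p = X.shape[1]
    beta = theta[:p]
    k = p
    if family in ("nb", "zinb"):
        phi = np.exp(theta[k])
        k += 1
    else:
        phi = None
    if family in ("zip", "zinb"):
        pi = 1.0 / (1.0 + np.exp(-theta[k]))
    else:
        pi = None

    eta = np.clip(X @ beta, -30.0, 30.0)  # overflow guard far from optimum
    mu = np.exp(eta)
    zero = y == 0
    grad = np.zeros_like(theta)

    if family == "poisson":
        ll = y * eta - mu - gammaln(y + 1.0)
        grad[:p] = X.T @ (y - mu)
        return -ll.sum(), -grad

    if family == "nb":
        ll = _nb_logpmf(y, mu, phi)
        grad[:p] = X.T @ ((y - mu) * phi / (phi + mu))
        dphi = (
            digamma(y + phi) - digamma(phi)
            + np.log(phi) - np.log(phi + mu) + 1.0 - (y + phi) / (phi + mu)
        )
        grad[p] = phi * dphi.sum()  # chain rule through log phi
        return -ll.sum(), -grad

    if family == "zip":
        log_p0 = -mu  # Poisson P(0)
        ll_pos = np.log1p(-pi) + y * eta - mu - gammaln(y + 1.0)
        ll_zero = np.logaddexp(np.log(pi), np.log1p(-pi) + log_p0)
        ll = np.where(zero, ll_zero, ll_pos)
        denom = pi + (1.0 - pi) * np.exp(log_p0)
        # d/d eta
        deta = np.where(
            zero, -(1.0 - pi) * np.exp(log_p0) * mu / denom, y - mu
        )
        grad[:p] = X.T @ deta
        dpi = np.where(zero, (1.0 - np.exp(log_p0)) / denom, -1.0 / (1.0 - pi))
        grad[p] = (pi * (1.0 - pi)) * dpi.sum()
        return -ll.sum(), -grad

    if family == "zinb":
        log_nb0 = phi * (np.log(phi) - np.log(phi + mu))  # NB P(0)
        nb_ll = _nb_logpmf(y, mu, phi)
        ll = np.where(
            zero,
            np.logaddexp(np.log(pi), np.log1p(-pi) + log_nb0),
            np.log1p(-pi) + nb_ll,
        )
        nb0 = np.exp(log_nb0)
        denom = pi + (1.0 - pi) * nb0
        w = phi / (phi + mu)
        # d log L / d eta
        deta = np.where(
            zero,
            -(1.0 - pi) * nb0 * mu * w / denom,
            (y - mu) * w,
        )
        grad[:p] = X.T @ deta
        # d log L / d phi
        dnb0_dphi = nb0 * (np.log(w) + mu / (phi + mu))
        dphi_pos = (
            digamma(y + phi) - digamma(phi)
            + np.log(w) + 1.0 - (y + phi) / (phi + mu)
        )
        dphi = np.where(zero, (1.0 - pi) * dnb0_dphi / denom, dphi_pos)
        grad[p] = phi * dphi.sum()
        dpi = np.where(zero, (1.0 - nb0) / denom, -1.0 / (1.0 - pi))
        grad[p + 1] = (pi * (1.0 - pi)) * dpi.sum()
        return -ll.sum(), -grad

    raise ValueError(f"unknown family {family!r}")


@dataclass
class CountModelFit:
    """A fitted count model: coefficients on the log link plus the family's
    auxiliary parameters, log-likelihood and AIC."""

    family: str
    predictors: tuple
    coefficients: pd.Series
    phi: float | None
    pi: float | None
    loglik: float
    aic: float
    df: int
    converged: bool
    n: int
    message: str = ""
    fitted_mean: np.ndarray | None = dc_field(default=None, repr=False)

    @property
    def name(self) -> str:
        return f"{self.family}(~{'+'.join(self.predictors)})"


def _poisson_warm_start(y, X):
    """Deterministic Poisson warm start: Newton iterations from the
    intercept-only solution (beta0 = log mean)."""
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(25):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def fit_count_model(table: TrapHaulTable, predictors, family: str) -> CountModelFit:
    """Maximum-likelihood fit of one of the four count families.

    The start is deterministic: beta from a Poisson warm start, log phi = 0,
    logit pi from the empirical excess-zero fraction.  On non-convergence
    the optimizer restarts once from a slightly jittered start (fixed seed);
    the fit is returned either way, flagged accordingly.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    predictors = tuple(predictors)
    y = table.counts.astype(np.float64)
    X, names = design_matrix(table, predictors)
    p = X.shape[1]
    if len(table) <= p + 2:
        raise DataError(f"{len(table)} records cannot support {p} coefficients")
    degenerate = [names[j] for j in range(1, p) if X[:, j].sum() == 0]
    if degenerate:
        import warnings

        warnings.warn(f"design columns with no observations: {degenerate}")

    beta0 = _poisson_warm_start(y, X)
    theta0 = list(beta0)
    if family in ("nb", "zinb"):
        theta0.append(0.0)  # log phi = 0
    if family in ("zip", "zinb"):
        zero_frac = float((y == 0).mean())
        expected0 = float(np.exp(-np.exp(np.clip(X @ beta0, -30, 30))).mean())
        pi0 = np.clip(zero_frac - expected0, 0.02, 0.90)
        theta0.append(float(np.log(pi0 / (1.0 - pi0))))
    theta0 = np.asarray(theta0)

    def _run(start):
        return minimize(
            _nll_and_grad, start, args=(y, X, family), jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "gtol": 1e-6, "ftol": 1e-12},
        )

    res = _run(theta0)
    if not res.success:
        jitter_rng = np.random.default_rng(12345)
        res2 = _run(theta0 + 0.05 * jitter_rng.standard_normal(theta0.size))
        if res2.fun < res.fun:
            res = res2

    theta = res.x
    beta = theta[:p]
    k = p
    phi = pi = None
    if family in ("nb", "zinb"):
        phi = float(np.exp(theta[k]))
        k += 1
    if family in ("zip", "zinb"):
        pi = float(1.0 / (1.0 + np.exp(-theta[k])))
    df = p + (phi is not None) + (pi is not None)
    loglik = -float(res.fun)
    return CountModelFit(
        family=family,
        predictors=predictors,
        coefficients=pd.Series(beta, index=names),
        phi=phi,
        pi=pi,
        loglik=loglik,
        aic=2.0 * df - 2.0 * loglik,
        df=df,
        converged=bool(res.success),
        n=len(table),
        message=str(res.message),
        fitted_mean=np.exp(X @ beta),
    )


def overdispersion_check(fit: CountModelFit, table: TrapHaulTable) -> float:
    """Pearson chi-square / residual df; values well above 1 flag
    overdispersion relative to the fitted family's variance."""
    y = table.counts.astype(float)
    mu = fit.fitted_mean
    if fit.pi is not None:
        mean = (1.0 - fit.pi) * mu
    else:
        mean = mu
    if fit.family in ("poisson", "zip"):
        var_count = mu
    else:
        var_count = mu + mu**2 / fit.phi
    if fit.pi is not None:
        var = (1.0 - fit.pi) * (var_count + fit.pi * mu**2)
    else:
        var = var_count
    resid_df = max(fit.n - fit.df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(var > 0, (y - mean) ** 2 / var, 0.0)
    return float(pearson.sum() / resid_df)


def ladder_formulas() -> list[tuple[str, tuple]]:
    """The simple (m1-m5) and cumulative (M1-M5) predictor ladders."""
    simple = [(f"m{i+1}", (pred,)) for i, pred in enumerate(PREDICTOR_ORDER)]
    cumulative = [
        (f"M{i+1}", tuple(PREDICTOR_ORDER[: i + 1]))
        for i in range(len(PREDICTOR_ORDER))
    ]
    return simple + cumulative


def model_selection(
    table: TrapHaulTable, candidates=None, family: str = "zinb"
) -> pd.DataFrame:
    """Fit every candidate (name, predictors) on the same records and rank by
    AIC ascending, ties broken by fewer parameters."""
    if candidates is None:
        candidates = ladder_formulas()
    rows = []
    fits = {}
    for name, predictors in candidates:
        try:
            fit = fit_count_model(table, predictors, family)
            fits[name] = fit
            rows.append(
                {
                    "model": name,
                    "covariates": "+".join(predictors),
                    "family": family,
                    "df": fit.df,
                    "aic": fit.aic,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                    "status": "ok",
                }
            )
        except (DataError, ValueError) as exc:  # keep the ladder going
            rows.append(
                {
                    "model": name,
                    "covariates": "+".join(predictors),
                    "family": family,
                    "df": np.nan,
                    "aic": np.inf,
                    "loglik": np.nan,
                    "converged": False,
                    "status": f"error: {exc}",
                }
            )
    out = pd.DataFrame(rows).sort_values(
        ["aic", "df"], kind="stable"
    ).reset_index(drop=True)
    out.attrs["fits"] = fits
    return out


def zinb_zero_probability(mu, phi: float, pi: float):
    """Analytic P(Y = 0) of the ZINB: pi + (1 - pi) (phi/(phi+mu))^phi."""
    mu = np.asarray(mu, dtype=float)
    return pi + (1.0 - pi) * (phi / (phi + mu)) ** phi
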