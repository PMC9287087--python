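"""Model fitting and marginal summaries.

Two model families are provided, matching the two kinds of response:

* Gaussian generalized least squares with a continuous-time AR(1)
  correlation structure (``corr(t_i, t_j) = phi**|t_i - t_j|`` within a
  correlation group, independence across groups), with the correlation
  parameter profiled out by bounded scalar search. Used for ratio-valued
  responses on an irregular monthly time axis.
* A quasi-binomial logit GLM for continuous proportions in [0, 1], fitted
  by iteratively reweighted least squares with unit prior weights and a
  Pearson-based dispersion estimate.

Factor-level estimated means, intervals and multiplicity-adjusted pairwise
contrasts are computed from either fit on a balanced reference grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_data import TimePeriodScheme

GAUSSIAN_CAR1 = "gaussian_car1"
QUASIBINOMIAL_LOGIT = "quasibinomial_logit"

_PHI_EPS = 1e-6


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignSpec:
    """Response + factor design on a (possibly irregular) monthly time axis.

    ``data`` must contain a ``value`` column, one column per entry of
    ``factors``, a real ``time`` column (months since the study start) and a
    ``group`` column delimiting correlation groups for the GLS family.
    """

    data: pd.DataFrame
    factors: tuple[str, ...] = ("period",)
    levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = {"value", "time", "group", *self.factors}
        missing = needed - set(self.data.columns)
        if missing:
            raise ValueError(f"design data missing columns: {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)
        for f in self.factors:
            if f not in self.levels:
                self.levels[f] = sorted(self.data[f].unique())
            if len(self.levels[f]) < 1:
                raise ValueError(f"factor {f!r} has no levels")

    @classmethod
    def from_metric(
        cls, series: pd.DataFrame, scheme: TimePeriodScheme
    ) -> "DesignSpec":
        """One-way design (period factor) from a labelled metric series.

        Invalid rows are excluded from the design (their reason codes stay
        in the exported metric tables).
        """
        from .metrics import label_periods

        df = series if "period_label" in series.columns else label_periods(series, scheme)
        df = df[df["valid"]].copy()
        data = pd.DataFrame(
            {
                "value": df["value"].to_numpy(),
                "period": df["period_label"].to_numpy(),
                "time": df["month_index"].to_numpy(dtype=float) - scheme.start.index,
                "group": df["period_label"].to_numpy(),
            }
        )
        present = set(data["period"])
        return cls(
            data,
            factors=("period",),
            levels={"period": [l for l in scheme.labels if l in present]},
        )

    @classmethod
    def from_metric_pair(
        cls,
        series_by_treatment: dict[str, pd.DataFrame],
        scheme: TimePeriodScheme,
        periods: Sequence[str] | None = None,
    ) -> "DesignSpec":
        """Two-factor design (period + treatment) from per-treatment series."""
        from .metrics import label_periods

        frames = []
        for treatment, series in series_by_treatment.items():
            df = (
                series
                if "period_label" in series.columns
                else label_periods(series, scheme)
            )
            df = df[df["valid"]].copy()
            if periods is not None:
                df = df[df["period_label"].isin(periods)]
            frames.append(
                pd.DataFrame(
                    {
                        "value": df["value"].to_numpy(),
                        "period": df["period_label"].to_numpy(),
                        "treatment": treatment,
                        "time": df["month_index"].to_numpy(dtype=float)
                        - scheme.start.index,
                        "group": df["period_label"].astype(str) + ":" + treatment,
                    }
                )
            )
        data = pd.concat(frames, ignore_index=True)
        lv = {
            "period": [p for p in scheme.labels if p in set(data["period"])],
            "treatment": sorted(series_by_treatment),
        }
        return cls(data, factors=("period", "treatment"), levels=lv)

    def matrix(self) -> tuple[np.ndarray, list[str]]:
        """Treatment-coded design matrix (intercept + non-reference dummies)."""
        n = len(self.data)
        cols = [np.ones(n)]
        names = ["(Intercept)"]
        for f in self.factors:
            for lev in self.levels[f][1:]:
                cols.append((self.data[f] == lev).to_numpy(dtype=float))
                names.append(f"{f}[{lev}]")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design (empty factor cell?)")
        return X, names

    def level_row(self, factor: str, level: str) -> np.ndarray:
        """emmeans-style contrast row for one level of ``factor``.

        Sets the factor's dummies at the level and averages the other
        factors over their levels with equal weight (balanced grid).
        """
        _, names = self.matrix()
        row = np.zeros(len(names))
        row[0] = 1.0
        for f in self.factors:
            levs = self.levels[f]
            for lev in levs[1:]:
                j = names.index(f"{f}[{lev}]")
                if f == factor:
                    row[j] = 1.0 if lev == level else 0.0
                else:
                    row[j] = 1.0 / len(levs)
        return row


# ---------------------------------------------------------------------------
# fits


@dataclass
class ModelFit:
    family: str
    coefficients: np.ndarray
    coef_names: list[str]
    coef_covariance: np.ndarray
    n: int
    df_residual: int
    phi: float | None = None
    sigma2: float | None = None
    dispersion: float | None = None
    loglik: float | None = None
    quasi_deviance: float | None = None
    method: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        C = self.coef_covariance
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("coefficient covariance not symmetric")

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.coef_covariance))
        return pd.DataFrame(
            {"term": self.coef_names, "estimate": self.coefficients, "se": se}
        )


def car1_correlation(
    times: np.ndarray, phi: float, groups: np.ndarray | None = None
) -> np.ndarray:
    """Continuous-time AR(1) correlation matrix.

    Entry (i, j) is ``phi ** |t_i - t_j|`` when i and j share a group and 0
    otherwise; the diagonal is 1 (also at phi = 0).
    """
    if not 0 <= phi < 1:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    gaps = np.abs(t[:, None] - t[None, :])
    with np.errstate(divide="ignore"):
        R = np.where(gaps == 0, 1.0, phi**gaps)
    if groups is not None:
        g = np.asarray(groups)
        same = g[:, None] == g[None, :]
        R = np.where(same, R, 0.0)
    return R


def _whiten(y, X, times, groups, phi):
    """Per-group CAR1 whitening. Returns stacked y*, X* and log|R|."""
    from scipy.linalg import solve_triangular

    yw_parts, Xw_parts = [], []
    logdet = 0.0
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        Rg = car1_correlation(times[idx], phi)
        L = np.linalg.cholesky(Rg)
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        yw_parts.append(solve_triangular(L, y[idx], lower=True))
        Xw_parts.append(solve_triangular(L, X[idx], lower=True))
    return np.concatenate(yw_parts), np.vstack(Xw_parts), logdet


def _gls_profile(y, X, times, groups, phi, method):
    """Profiled (negative) log-likelihood and GLS estimates at fixed phi."""
    n, p = X.shape
    yw, Xw, logdetR = _whiten(y, X, times, groups, phi)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if method == "REML":
        sigma2 = rss / (n - p)
        sign, logdetXtX = np.linalg.slogdet(XtX)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma2) + logdetR + logdetXtX + (n - p)
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetR + n)
    return ll, beta, XtX, rss


def fit_gls_car1(
    design: DesignSpec,
    method: str = "REML",
    fixed_phi: float | None = None,
) -> ModelFit:
    """GLS with CAR1 errors; phi profiled by bounded scalar search.

    For each candidate phi the coefficients and scale are profiled out in
    closed form; phi is then optimized on [0, 1 - 1e-6] by Brent search
    (convergence 1e-8), with the phi = 0 endpoint checked explicitly.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be REML or ML, got {method!r}")
    X, names = design.matrix()
    y = design.data["value"].to_numpy(dtype=float)
    times = design.data["time"].to_numpy(dtype=float)
    groups = design.data["group"].to_numpy()
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations, have {n}")

    if fixed_phi is not None:
        phi_hat = float(fixed_phi)
    else:
        def nll(phi):
            return -_gls_profile(y, X, times, groups, phi, method)[0]

        res = optimize.minimize_scalar(
            nll, bounds=(0.0, 1.0 - _PHI_EPS), method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:  # pragma: no cover - bounded search rarely fails
            raise RuntimeError(f"phi optimization failed: {res.message}")
        phi_hat = float(res.x)
        # boundary check: the profile can be monotone into phi = 0
        if nll(0.0) <= res.fun:
            phi_hat = 0.0

    ll, beta, XtX, rss = _gls_profile(y, X, times, groups, phi_hat, method)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    return ModelFit(
        family=GAUSSIAN_CAR1,
        coefficients=beta,
        coef_names=names,
        coef_covariance=cov,
        n=n,
        df_residual=n - p,
        phi=phi_hat,
        sigma2=sigma2,
        loglik=float(ll),
        method=method,
    )


def _quasi_deviance(y, mu):
    """Binomial-form deviance for continuous y in [0, 1]; 0*log(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def fit_proportion_glm(design: DesignSpec, max_iter: int = 100, tol: float = 1e-10) -> ModelFit:
    """Quasi-binomial logit GLM on continuous proportions, via IRLS.

    Unit prior weights; dispersion by Pearson chi-square over residual df;
    step-halving enforces a monotone quasi-deviance decrease. Responses of
    exactly 0 or 1 are handled by the working-response formulation. Cells
    fitted at the boundary are flagged, not errors.
    """
    X, names = design.matrix()
    y = design.data["value"].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportion responses must lie in [0, 1]")
    n, p = X.shape

    mu = np.clip(y, 1e-3, 1 - 1e-3) * 0.5 + 0.25  # mild shrink toward 0.5
    eta = special.logit(mu)
    beta = np.zeros(p)
    dev = _quasi_deviance(y, mu)
    for _ in range(max_iter):
        W = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / W
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        step = beta_new - beta
        # step-halving on quasi-deviance
        for _half in range(30):
            cand = beta + step
            eta_c = np.clip(X @ cand, -30, 30)
            mu_c = special.expit(eta_c)
            dev_c = _quasi_deviance(y, np.clip(mu_c, 1e-12, 1 - 1e-12))
            if dev_c <= dev + 1e-12:
                break
            step = step / 2.0
        beta, eta, mu = cand, eta_c, mu_c
        if abs(dev - dev_c) < tol * (abs(dev) + 1e-12):
            dev = dev_c
            break
        dev = dev_c

    mu_s = np.clip(mu, 1e-12, 1 - 1e-12)
    pearson = float(np.sum((y - mu_s) ** 2 / (mu_s * (1 - mu_s))))
    dispersion = pearson / (n - p)
    W = mu_s * (1 - mu_s)
    cov = dispersion * np.linalg.inv(X.T @ (X * W[:, None]))
    flags = []
    if np.any(mu < 1e-6) or np.any(mu > 1 - 1e-6):
        flags.append("boundary")
    return ModelFit(
        family=QUASIBINOMIAL_LOGIT,
        coefficients=beta,
        coef_names=names,
        coef_covariance=cov,
        n=n,
        df_residual=n - p,
        dispersion=dispersion,
        quasi_deviance=dev,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# marginal summaries


@dataclass
class MarginalSummary:
    means: pd.DataFrame
    contrasts: pd.DataFrame
    adjust: str


def _adjusted_p(tstat: float, k: int, df: int, adjust: str) -> float:
    """p-value for one of the k-choose-2 pairwise contrasts."""
    if adjust == "tukey":
        return float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, df))
    p_raw = 2.0 * float(stats.t.sf(abs(tstat), df))
    if adjust == "bonferroni":
        return min(1.0, p_raw * (k * (k - 1) // 2))
    if adjust == "none":
        return p_raw
    raise ValueError(f"unknown adjustment {adjust!r}")


def marginal_means(
    fit: ModelFit, design: DesignSpec, adjust: str = "tukey", conf: float = 0.95
) -> MarginalSummary:
    """Factor-level estimated means, intervals and pairwise contrasts.

    Estimates are computed on the linear-predictor scale over a balanced
    reference grid (other factors averaged with equal level weights) and,
    for the GLM family, back-transformed through the inverse logit;
    intervals use a t reference with the fit's residual df. Contrasts stay
    on the link scale with the chosen multiplicity adjustment
    ("tukey" | "bonferroni" | "none").
    """
    tcrit = stats.t.ppf(0.5 + conf / 2.0, fit.df_residual)
    is_glm = fit.family == QUASIBINOMIAL_LOGIT
    inv = special.expit if is_glm else (lambda x: x)

    mean_rows, contrast_rows = [], []
    for factor in design.factors:
        levs = design.levels[factor]
        if any((design.data[factor] == lev).sum() == 0 for lev in levs):
            raise ValueError(f"factor {factor!r} has an empty level")
        link_est, link_se = {}, {}
        for lev in levs:
            L = design.level_row(factor, lev)
            est = float(L @ fit.coefficients)
            se = float(np.sqrt(L @ fit.coef_covariance @ L))
            link_est[lev], link_se[lev] = est, se
            mean_rows.append(
                {
                    "factor": factor,
                    "level": lev,
                    "estimate": float(inv(est)),
                    "lower": float(inv(est - tcrit * se)),
                    "upper": float(inv(est + tcrit * se)),
                    "link_estimate": est,
                    "link_se": se,
                }
            )
        k = len(levs)
        for a, b in itertools.combinations(levs, 2):
            La = design.level_row(factor, a)
            Lb = design.level_row(factor, b)
            D = La - Lb
            diff = float(D @ fit.coefficients)
            se = float(np.sqrt(D @ fit.coef_covariance @ D))
            # a saturated/noise-free fit can have zero dispersion
            tstat = diff / se if se > 0 else (0.0 if diff == 0 else np.inf * np.sign(diff))
            contrast_rows.append(
                {
                    "factor": factor,
                    "contrast": f"{a} - {b}",
                    "estimate": diff,
                    "se": se,
                    "t": tstat,
                    "df": fit.df_residual,
                    "p_adjusted": _adjusted_p(tstat, k, fit.df_residual, adjust)
                    if k > 1
                    else np.nan,
                }
            )
    return MarginalSummary(
        means=pd.DataFrame(mean_rows),
        contrasts=pd.DataFrame(contrast_rows),
        adjust=adjust,
    )


def compare_correlation_structures(design: DesignSpec) -> pd.DataFrame:
    """AIC comparison of independent vs CAR1 errors (ML fits).

    A deliberately minimal selection step: both structures are fitted by
    maximum likelihood and ranked by AIC (parameter counts p+1 and p+2).
    """
    if len(design.data) < 5:
        raise ValueError("need at least 5 observations to compare structures")
    rows = []
    for structure, fixed in (("independence", 0.0), ("car1", None)):
        fit = fit_gls_car1(design, method="ML", fixed_phi=fixed)
        n_par = len(fit.coefficients) + 1 + (0 if structure == "independence" else 1)
        rows.append(
            {
                "structure": structure,
                "loglik": fit.loglik,
                "n_parameters": n_par,
                "AIC": -2 * fit.loglik + 2 * n_par,
                "phi": fit.phi,
            }
        )
    out = pd.DataFrame(rows)
    out["selected"] = out["AIC"] == out["AIC"].min()
    return out


def simulate_car1_noise(
    times: np.ndarray, groups: np.ndarray, phi: float, sigma: float, rng
) -> np.ndarray:
    """Draw a mean-zero Gaussian vector with the CAR1 covariance.

    Utility for calibration/recovery experiments; uses the exact stationary
    AR(1) recursion per group, valid for irregular gaps.
    """
    t = np.asarray(times, dtype=float)
    out = np.empty(len(t))
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        order = idx[np.argsort(t[idx])]
        prev = rng.normal(0.0, sigma)
        out[order[0]] = prev
        for i, j in zip(order, order[1:]):
            rho = phi ** (t[j] - t[i])
            prev = rho * prev + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0.0, sigma)
            out[j] = prev
    return out
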