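"""Inferential layer: group comparisons with covariate adjustment.

The central object is :class:`CoherenceModel`, an OLS linear model of a
per-post response (coherence by default) on a dummy-coded group factor plus
text covariates, in the statsmodels mould: the model is built from a
DataFrame, ``fit()`` returns a :class:`CoherenceResults` carrying
coefficients, standard errors, t/p-values, adjusted R², partial eta², and
the machinery for estimated marginal means (EMMs), Tukey-adjusted pairwise
contrasts with Cohen's d, and a text ``summary()``.

Estimated marginal means are model predictions per group with every
covariate held at its grand mean over the estimation sample; their standard
errors come from the coefficient covariance through the prediction-vector
quadratic form.  Pairwise EMM contrasts are Tukey-adjusted through the
studentized range distribution, whose tail probability is evaluated here by
Gauss-Legendre quadrature of the closed-form density; for two groups the
adjustment reduces exactly to the unadjusted two-sided t-test, and that
identity is special-cased so it holds to machine precision.

Also provided: Welch (default) and pooled two-sample t-tests with Cohen's
d, and post-hoc power for a two-group comparison via the noncentral t
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "two_sample_t",
    "studentized_range_sf",
    "studentized_range_crit",
    "tukey_adjusted_p",
    "CoherenceModel",
    "CoherenceResults",
    "posthoc_power_two_group",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ["word_count", "sentence_count", "sentence_length", "valence", "subjectivity"]

ALPHA = 0.05  # conventional significance threshold used in summaries


# ---------------------------------------------------------------------------
# two-sample t-test


@dataclass(frozen=True)
class TTestResult:
    """Two-sided two-sample t-test with Cohen's d."""

    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    mean_diff: float
    d: float
    d_ci_low: float
    d_ci_high: float
    equal_var: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        if not self.ci_low <= self.mean_diff <= self.ci_high:
            raise ValueError("CI does not contain the point estimate")


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    *,
    equal_var: bool = False,
    conf_level: float = 0.95,
) -> TTestResult:
    """Two-sided t-test for a difference in means, Welch by default.

    Welch uses the Satterthwaite degrees of freedom; ``equal_var=True``
    switches to the pooled-variance (Student) test.  Cohen's d always uses
    the pooled SD as standardizer, with the large-sample variance
    approximation for its confidence interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("both samples have zero variance")
    diff = float(x.mean() - y.mean())
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        df = float((a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1)))
    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.5 + conf_level / 2.0, df))
    # pooled-SD Cohen's d with large-sample CI
    sp = float(np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)))
    d = diff / sp
    se_d = float(np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))))
    z = float(sps.norm.ppf(0.5 + conf_level / 2.0))
    return TTestResult(
        t=float(t),
        df=df,
        p=min(1.0, p),
        ci_low=diff - tcrit * float(se),
        ci_high=diff + tcrit * float(se),
        mean_diff=diff,
        d=float(d),
        d_ci_low=float(d - z * se_d),
        d_ci_high=float(d + z * se_d),
        equal_var=equal_var,
    )


# ---------------------------------------------------------------------------
# studentized range distribution (Tukey adjustment)

_Z_NODES = 160
_U_NODES = 80

_LEGGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    got = _LEGGAUSS_CACHE.get(n)
    if got is None:
        got = _LEGGAUSS_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return got


def _range_cdf_std(w: np.ndarray, k: int) -> np.ndarray:
    """P(range of k iid N(0,1) <= w), vectorized over w >= 0."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    out = np.zeros_like(w)
    pos = w > 0
    if np.any(pos):
        wp = w[pos]
        lo, hi = -9.0, 9.0 + float(wp.max())
        nodes, weights = _leggauss(_Z_NODES)
        z = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)  # (m,)
        phi = sps.norm.pdf(z)
        # integrand: k * phi(z) * (Phi(z) - Phi(z - w))^(k-1)
        inner = sps.norm.cdf(z)[None, :] - sps.norm.cdf(z[None, :] - wp[:, None])
        vals = k * phi[None, :] * np.clip(inner, 0.0, 1.0) ** (k - 1)
        out[pos] = 0.5 * (hi - lo) * vals @ weights
    return np.clip(out, 0.0, 1.0)


_CHI_NODES_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _chi_scaled_nodes(df: float) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for u = s/sigma ~ chi_df / sqrt(df) (cached)."""
    got = _CHI_NODES_CACHE.get(df)
    if got is not None:
        return got
    u_lo = sps.chi.ppf(1e-12, df) / np.sqrt(df)
    u_hi = sps.chi.ppf(1.0 - 1e-12, df) / np.sqrt(df)
    nodes, weights = _leggauss(_U_NODES)
    u = 0.5 * (u_hi - u_lo) * nodes + 0.5 * (u_hi + u_lo)
    # log density of u: chi_df scaled by 1/sqrt(df)
    logg = (
        (df / 2.0) * np.log(df)
        - special.gammaln(df / 2.0)
        - (df / 2.0 - 1.0) * np.log(2.0)
        + (df - 1.0) * np.log(u)
        - df * u**2 / 2.0
    )
    out = (u, 0.5 * (u_hi - u_lo) * weights * np.exp(logg))
    if len(_CHI_NODES_CACHE) < 256:
        _CHI_NODES_CACHE[df] = out
    return out


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """P(Q_{k, df} >= q): studentized-range survival function.

    Evaluated by Gauss-Legendre quadrature of the closed-form density
    (outer integral over the scaled chi variable, inner over the normal
    range); ``df=inf`` (or very large df) uses the limiting normal range.
    k=2 uses the exact identity with the t distribution.
    """
    if k < 2:
        raise ValueError("studentized range needs k >= 2")
    if q <= 0:
        return 1.0
    if k == 2:
        # Q = sqrt(2) |T| exactly
        return float(min(1.0, 2.0 * sps.t.sf(q / np.sqrt(2.0), df)))
    if not np.isfinite(df) or df > 1e7:
        return float(1.0 - _range_cdf_std(np.array([q]), k)[0])
    u, w = _chi_scaled_nodes(float(df))
    cdf = float(np.sum(w * _range_cdf_std(q * u, k)))
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def studentized_range_crit(alpha: float, k: int, df: float) -> float:
    """Upper critical value q with P(Q_{k,df} >= q) = alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(
        optimize.brentq(lambda q: studentized_range_sf(q, k, df) - alpha, 1e-8, 200.0)
    )


def tukey_adjusted_p(t_ratio: float, k: int, df: float) -> float:
    """Tukey-adjusted p for one pairwise contrast among k group means."""
    if k == 2:
        return float(min(1.0, 2.0 * sps.t.sf(abs(t_ratio), df)))
    return studentized_range_sf(abs(t_ratio) * np.sqrt(2.0), k, df)


# ---------------------------------------------------------------------------
# OLS model with EMMs and Tukey pairwise contrasts


class CoherenceModel:
    """OLS of a per-post response on group dummies plus covariates.

    Parameters
    ----------
    y : response vector.
    groups : group label per row.
    covariates : (n, m) covariate matrix (may have zero columns).
    covariate_names : column names for reporting.
    reference_group : dummy-coding reference; default = first sorted label.
    """

    def __init__(
        self,
        y: np.ndarray,
        groups: Sequence[str],
        covariates: np.ndarray,
        covariate_names: Sequence[str],
        reference_group: str | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.groups = np.asarray(groups, dtype=object)
        self.covariates = np.asarray(covariates, dtype=float).reshape(len(self.y), -1)
        self.covariate_names = list(covariate_names)
        levels = sorted(set(self.groups))
        if len(levels) < 1:
            raise ValueError("no group labels")
        if reference_group is None:
            reference_group = levels[0]
        if reference_group not in levels:
            raise ValueError(f"reference group {reference_group!r} not among {levels}")
        self.reference_group = reference_group
        self.levels = [reference_group] + [g for g in levels if g != reference_group]
        n = len(self.y)
        dummies = np.zeros((n, len(self.levels) - 1))
        for j, g in enumerate(self.levels[1:]):
            dummies[:, j] = self.groups == g
        self.exog_names = (
            ["Intercept"]
            + [f"group[{g}]" for g in self.levels[1:]]
            + self.covariate_names
        )
        self.X = np.column_stack([np.ones(n), dummies, self.covariates])

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str = "coherence",
        group_col: str = "group",
        covariates: Sequence[str] | None = None,
        reference_group: str | None = None,
    ) -> "CoherenceModel":
        if covariates is None:
            covariates = [c for c in DEFAULT_COVARIATES if c in data.columns]
        return cls(
            y=data[response].to_numpy(dtype=float),
            groups=data[group_col].astype(str).to_numpy(),
            covariates=data.loc[:, list(covariates)].to_numpy(dtype=float),
            covariate_names=list(covariates),
            reference_group=reference_group,
        )

    def fit(self) -> "CoherenceResults":
        X, y = self.X, self.y
        n, p = X.shape
        if n <= p:
            raise ValueError(f"n={n} must exceed the {p} coefficients")
        Q, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        deficient = np.where(diag <= tol)[0]
        if deficient.size:
            names = [self.exog_names[i] for i in deficient]
            raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")
        beta = np.linalg.solve(R, Q.T @ y)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df_resid = n - p
        sigma2 = rss / df_resid
        Rinv = np.linalg.solve(R, np.eye(p))
        xtx_inv = Rinv @ Rinv.T
        cov_params = sigma2 * xtx_inv
        bse = np.sqrt(np.diag(cov_params))
        tvals = beta / bse
        pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)
        tss = float(((y - y.mean()) ** 2).sum())
        rsq = 1.0 - rss / tss if tss > 0 else 0.0
        adj = 1.0 - (1.0 - rsq) * (n - 1) / df_resid
        return CoherenceResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            tvalues=pd.Series(tvals, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            cov_params=pd.DataFrame(cov_params, index=self.exog_names, columns=self.exog_names),
            df_resid=df_resid,
            sigma2=sigma2,
            rsquared=rsq,
            rsquared_adj=adj,
            nobs=n,
        )


@dataclass
class CoherenceResults:
    """Fit artifacts plus EMM / Tukey-contrast machinery."""

    model: CoherenceModel
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    df_resid: int
    sigma2: float
    rsquared: float
    rsquared_adj: float
    nobs: int

    @property
    def sigma(self) -> float:
        """Residual standard deviation."""
        return float(np.sqrt(self.sigma2))

    @property
    def partial_eta_sq(self) -> pd.Series:
        """Partial eta^2 per coefficient: t^2 / (t^2 + df_resid)."""
        t2 = self.tvalues**2
        return t2 / (t2 + self.df_resid)

    @property
    def covariate_grand_means(self) -> np.ndarray:
        return self.model.covariates.mean(axis=0) if self.model.covariates.size else np.empty(0)

    def _emm_row(self, group: str) -> np.ndarray:
        """Prediction vector for one group at covariate grand means."""
        levels = self.model.levels
        if group not in levels:
            raise ValueError(f"group {group!r} not in fitted model (levels: {levels})")
        x = np.zeros(len(self.params))
        x[0] = 1.0
        if group != levels[0]:
            x[1 + levels[1:].index(group)] = 1.0
        x[len(levels) :] = self.covariate_grand_means
        return x

    def emmeans(self) -> pd.DataFrame:
        """Estimated marginal mean and SE per group (covariates at grand means)."""
        cov = self.cov_params.to_numpy()
        beta = self.params.to_numpy()
        rows = []
        for g in sorted(self.model.levels):
            x = self._emm_row(g)
            rows.append(
                {"group": g, "emmean": float(x @ beta), "se": float(np.sqrt(x @ cov @ x))}
            )
        return pd.DataFrame(rows)

    def pairwise(self, conf_level: float = 0.95) -> pd.DataFrame:
        """Tukey-adjusted pairwise EMM contrasts with Cohen's d.

        Cohen's d standardizes the EMM difference by the model residual SD;
        its CI uses the large-sample normal approximation.
        """
        levels = sorted(self.model.levels)
        k = len(levels)
        if k < 2:
            raise ValueError("pairwise contrasts need k >= 2 groups")
        cov = self.cov_params.to_numpy()
        beta = self.params.to_numpy()
        sigma = self.sigma
        z = float(sps.norm.ppf(0.5 + conf_level / 2.0))
        rows = []
        for g1, g2 in combinations(levels, 2):
            c = self._emm_row(g1) - self._emm_row(g2)
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t_ratio = diff / se
            p_adj = tukey_adjusted_p(t_ratio, k, self.df_resid)
            d = diff / sigma
            se_d = se / sigma
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "estimate": diff,
                    "se": se,
                    "t_ratio": t_ratio,
                    "p_tukey": p_adj,
                    "cohens_d": d,
                    "d_ci_low": d - z * se_d,
                    "d_ci_high": d + z * se_d,
                }
            )
        return pd.DataFrame(rows)

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        return (self.model.X if X is None else np.asarray(X)) @ self.params.to_numpy()

    def summary(self) -> str:
        """Readable fit report: coefficients, fit statistics, EMMs, contrasts."""
        lines = [
            "OLS group-comparison model",
            "=" * 78,
            f"N obs: {self.nobs}    residual df: {self.df_resid}    "
            f"sigma: {self.sigma:.6g}",
            f"R^2: {self.rsquared:.4f}    adj. R^2: {self.rsquared_adj:.4f}",
            f"reference group: {self.model.reference_group}",
            "-" * 78,
            f"{'term':<24}{'coef':>12}{'se':>12}{'t':>10}{'p':>12}{'eta2p':>8}",
        ]
        eta = self.partial_eta_sq
        for name in self.params.index:
            lines.append(
                f"{name:<24}{self.params[name]:>12.5g}{self.bse[name]:>12.3g}"
                f"{self.tvalues[name]:>10.2f}{self.pvalues[name]:>12.3g}{eta[name]:>8.4f}"
            )
        lines.append("-" * 78)
        lines.append("Estimated marginal means (covariates at grand means):")
        for _, r in self.emmeans().iterrows():
            lines.append(f"  {r['group']:<20} {r['emmean']:.5f} [SE {r['se']:.5f}]")
        if len(self.model.levels) >= 2:
            lines.append("Tukey-adjusted pairwise contrasts:")
            for _, r in self.pairwise().iterrows():
                lines.append(
                    f"  {r['group1']} - {r['group2']}: diff {r['estimate']:+.5f} "
                    f"(SE {r['se']:.5f}), t {r['t_ratio']:+.2f}, p {r['p_tukey']:.3g}, "
                    f"d {r['cohens_d']:+.3f} [{r['d_ci_low']:+.3f}, {r['d_ci_high']:+.3f}]"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# post-hoc power


def posthoc_power_two_group(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at effect size d.

    Uses the noncentral t distribution with noncentrality
    d * sqrt(n1 n2 / (n1 + n2)) and pooled df n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(min(1.0, max(0.0, power)))
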