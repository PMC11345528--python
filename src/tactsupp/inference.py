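"""Group-level inference: random-intercept linear mixed models with
Satterthwaite F tests, Bonferroni-adjusted marginal-mean contrasts with
Cohen's d, Spearman correlation families, and the a-priori power
computation.

The mixed model is ``response ~ movement * cue (+ amplitude)`` with a
participant random intercept, fitted by maximum likelihood (statsmodels
MixedLM).  Type-III F tests and per-contrast denominator degrees of
freedom use the Satterthwaite approximation computed in-package from the
fitted variance components:

    df(l) = 2 * [l' C(theta) l]^2 / Var[l' C(theta_hat) l]

where ``C(theta)`` is the GLS covariance of the fixed effects and the
variance in the denominator comes from the delta method with the
asymptotic covariance of the variance-component estimates (numeric
Hessian of the profiled log-likelihood).  Multi-degree-of-freedom F tests
aggregate the per-eigencontrast dfs in the usual way.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM

from .exceptions import SingularDesignError, TactsuppError

DEFAULT_REFERENCES = {"movement": "baseline", "session_cue": "cue-"}


# ---------------------------------------------------------------------------
# random-intercept GLS engine
# ---------------------------------------------------------------------------


class _RandomInterceptGLS:
    """Closed-form GLS quantities for a random-intercept model.

    For group ``i`` with ``n_i`` rows, ``V_i = sigma2*I + tau2*J`` and
    ``V_i^{-1} = (I - k_i*J)/sigma2`` with ``k_i = tau2/(sigma2 + n_i*tau2)``,
    so all score/likelihood quantities reduce to per-group cross products.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = np.asarray(y, float).ravel()
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        codes, _ = pd.factorize(groups)
        G = codes.max() + 1
        self.ng = np.bincount(codes, minlength=G).astype(float)
        # per-group cross products, stacked for vectorized evaluation
        self.S = np.zeros((G, self.p))  # X_i' 1
        self.ysum = np.zeros(G)
        for j in range(self.p):
            self.S[:, j] = np.bincount(codes, weights=self.X[:, j], minlength=G)
        self.ysum = np.bincount(codes, weights=self.y, minlength=G)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _xtvix(self, tau2: float, sigma2: float):
        k = tau2 / (sigma2 + self.ng * tau2)
        XtVX = (self.XtX - self.S.T @ (k[:, None] * self.S)) / sigma2
        XtVy = (self.Xty - self.S.T @ (k * self.ysum)) / sigma2
        yVy = (self.yty - float(k @ self.ysum**2)) / sigma2
        logdet = float(
            np.sum((self.ng - 1) * np.log(sigma2) + np.log(sigma2 + self.ng * tau2))
        )
        return XtVX, XtVy, yVy, logdet

    def beta_and_cov(self, tau2: float, sigma2: float):
        XtVX, XtVy, _, _ = self._xtvix(tau2, sigma2)
        C = np.linalg.inv(XtVX)
        return C @ XtVy, C

    def profile_loglik(self, tau2: float, sigma2: float) -> float:
        XtVX, XtVy, yVy, logdet = self._xtvix(tau2, sigma2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - XtVy @ beta
        return -0.5 * (logdet + rss + self.n * np.log(2 * np.pi))


class _Satterthwaite:
    """Satterthwaite denominator dfs for contrasts of a random-intercept fit."""

    def __init__(self, gls: _RandomInterceptGLS, tau2: float, sigma2: float):
        self.gls = gls
        self.tau2 = max(tau2, 1e-10)
        self.sigma2 = sigma2
        self.eta = np.log([self.tau2, self.sigma2])  # work on log scale
        self.beta, self.C = gls.beta_and_cov(self.tau2, self.sigma2)
        self.vcov_eta = self._vcov_eta()

    def _loglik_eta(self, eta: np.ndarray) -> float:
        return self.gls.profile_loglik(*np.exp(eta))

    def _vcov_eta(self) -> np.ndarray:
        h = 1e-4
        H = np.zeros((2, 2))
        f0 = self._loglik_eta(self.eta)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h
                ej = np.eye(2)[j] * h
                H[i, j] = H[j, i] = (
                    self._loglik_eta(self.eta + ei + ej)
                    - self._loglik_eta(self.eta + ei - ej)
                    - self._loglik_eta(self.eta - ei + ej)
                    + self._loglik_eta(self.eta - ei - ej)
                ) / (4 * h * h)
        # observed information; guard singular boundary fits
        try:
            A = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(-H)
        if not np.all(np.isfinite(A)):
            A = np.zeros((2, 2))
        _ = f0
        return A

    def _var_of_lCl(self, ell: np.ndarray) -> float:
        h = 1e-4
        grad = np.zeros(2)
        for i in range(2):
            e = np.eye(2)[i] * h
            _, Cp = self.gls.beta_and_cov(*np.exp(self.eta + e))
            _, Cm = self.gls.beta_and_cov(*np.exp(self.eta - e))
            grad[i] = (ell @ Cp @ ell - ell @ Cm @ ell) / (2 * h)
        return float(grad @ self.vcov_eta @ grad)

    def df_contrast(self, ell: np.ndarray) -> float:
        f = float(ell @ self.C @ ell)
        v = self._var_of_lCl(ell)
        if v <= 0 or not np.isfinite(v):
            return float(self.gls.n - self.gls.p)
        return float(np.clip(2 * f * f / v, 1.0, 1e7))

    def t_test(self, ell: np.ndarray) -> tuple[float, float, float, float]:
        """(estimate, se, t, df) for the scalar contrast ``ell @ beta``."""
        est = float(ell @ self.beta)
        se = float(np.sqrt(ell @ self.C @ ell))
        df = self.df_contrast(ell)
        return est, se, est / se, df

    def f_test(self, L: np.ndarray) -> tuple[float, float, float]:
        """(F, df_num, df_den) for the joint hypothesis ``L @ beta = 0``."""
        L = np.atleast_2d(np.asarray(L, float))
        q = L.shape[0]
        M = L @ self.C @ L.T
        Minv = np.linalg.inv(M)
        F = float((L @ self.beta) @ Minv @ (L @ self.beta) / q)
        # per-eigencontrast Satterthwaite dfs, aggregated
        vals, vecs = np.linalg.eigh(M)
        nus = []
        for m in range(q):
            ell = L.T @ vecs[:, m]
            nus.append(self.df_contrast(ell))
        E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
        if E <= q:
            df_den = float(self.gls.n - self.gls.p)
        else:
            df_den = float(np.clip(2.0 * E / (E - q), 1.0, 1e7))
        return F, float(q), df_den


# ---------------------------------------------------------------------------
# model specification and results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fixed-effect F table, coefficient table and fit diagnostics."""

    response: str
    anova: pd.DataFrame  # term, SS, MS, df_num, df_den, F, p
    coefficients: pd.DataFrame  # term, estimate, se
    loglik: float
    converged: bool
    sigma2: float
    tau2: float
    reference_levels: dict = field(default_factory=dict)
    model: "MixedModelAnalysis | None" = None


class MixedModelAnalysis(BaseEstimator):
    """Random-intercept LMM with Satterthwaite Type-III F tests.

    Parameters
    ----------
    response : column with the dependent variable (e.g. ``d_prime``).
    factors : fixed factors, crossed with interaction (dummy coded with
        the stated reference levels in the coefficient table).
    covariate : optional numeric covariate of no interest (uncentered;
        marginal means are evaluated at its grand mean).
    group : column identifying the random-intercept grouping (participant).

    Fitted attributes: ``anova_`` (term, SS, MS, df_num, df_den, F, p),
    ``coef_``, ``loglik_``, ``converged_``, ``sigma2_``, ``tau2_``.
    SS/MS follow the mixed-model convention SS = F * df_num * sigma2, so
    MS / sigma2 reproduces F.
    """

    def __init__(
        self,
        response: str = "d_prime",
        factors: tuple[str, ...] = ("movement", "session_cue"),
        covariate: str | None = "amplitude_mm",
        group: str = "participant_id",
        reference_levels: dict | None = None,
        alpha: float = 0.05,
        cohens_d_method: str = "t2d",
    ):
        self.response = response
        self.factors = factors
        self.covariate = covariate
        self.group = group
        self.reference_levels = reference_levels
        self.alpha = alpha
        self.cohens_d_method = cohens_d_method

    # -- formula construction -------------------------------------------------

    def _refs(self) -> dict:
        refs = dict(DEFAULT_REFERENCES)
        if self.reference_levels:
            refs.update(self.reference_levels)
        return refs

    def _formula(self, coding: str) -> str:
        refs = self._refs()
        terms = []
        for f in self.factors:
            if coding == "treatment":
                ref = refs.get(f)
                terms.append(
                    f"C({f}, Treatment({ref!r}))" if ref is not None else f"C({f})"
                )
            else:
                terms.append(f"C({f}, Sum)")
        rhs = " * ".join(terms)
        if self.covariate:
            rhs += f" + {self.covariate}"
        return f"{self.response} ~ {rhs}"

    # -- fitting --------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        df = X.copy()
        needed = [self.response, self.group, *self.factors]
        if self.covariate:
            needed.append(self.covariate)
        missing = set(needed) - set(df.columns)
        if missing:
            raise ValueError(f"model table missing columns {sorted(missing)}")
        if "excluded" in df.columns:
            df = df[~df["excluded"].astype(bool)]
        df = df.dropna(subset=needed)
        if df[self.group].nunique() < 2:
            raise ValueError("need >= 2 participants for a mixed model")

        y_t, X_t = patsy.dmatrices(self._formula("treatment"), df, return_type="dataframe")
        X_s = patsy.dmatrix(self._formula("sum").split("~")[1], df, return_type="dataframe")
        if np.linalg.matrix_rank(X_t.to_numpy()) < X_t.shape[1]:
            raise SingularDesignError("fixed-effect design matrix is rank deficient")

        groups = df[self.group].to_numpy()
        endog = y_t.to_numpy().ravel()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = MixedLM(endog, X_t.to_numpy(), groups=groups)
            try:
                res = mod.fit(reml=False, method="lbfgs")
                if not res.converged:
                    res = mod.fit(reml=False, method="powell")
            except Exception:
                res = mod.fit(reml=False, method="powell")
        converged = bool(res.converged)
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        sigma2 = float(res.scale)

        # Polish the two variance components on the exact profiled ML
        # objective: the generic optimizer can stall near the tau2 = 0
        # boundary, while the profile surface is cheap in closed form.
        gls0 = _RandomInterceptGLS(endog, X_t.to_numpy(), groups)
        var_y = float(np.var(endog))
        starts = [
            (max(tau2, 1e-8 * var_y), sigma2),
            (0.1 * var_y, 0.9 * var_y),
        ]
        best = None
        for t0, s0 in starts:
            opt = optimize.minimize(
                lambda th: -gls0.profile_loglik(np.exp(th[0]), np.exp(th[1])),
                x0=np.log([t0, s0]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
            )
            if best is None or opt.fun < best.fun:
                best = opt
        tau2_hat, sigma2_hat = np.exp(best.x)
        self.converged_ = converged or bool(best.success)
        self.loglik_ = float(-best.fun)
        self.sigma2_ = float(sigma2_hat)
        self.tau2_ = float(tau2_hat)

        self._df = df
        self._design_info_t = X_t.design_info
        self._design_info_s = X_s.design_info
        self._satt_t = _Satterthwaite(gls0, self.tau2_, self.sigma2_)
        gls_s = _RandomInterceptGLS(endog, X_s.to_numpy(), groups)
        self._satt_s = _Satterthwaite(gls_s, self.tau2_, self.sigma2_)

        # coefficient table (treatment coding, reference levels as stated)
        self.coef_ = pd.DataFrame(
            {
                "term": list(X_t.design_info.column_names),
                "estimate": self._satt_t.beta,
                "se": np.sqrt(np.diag(self._satt_t.C)),
            }
        )

        # Type-III F table: in the sum-to-zero parameterization, each
        # term's Type-III hypothesis is that its own coefficients vanish.
        rows = []
        slices = X_s.design_info.term_name_slices
        p = X_s.shape[1]
        for term, sl in slices.items():
            if term == "Intercept":
                continue
            L = np.zeros((sl.stop - sl.start, p))
            for r, c in enumerate(range(sl.start, sl.stop)):
                L[r, c] = 1.0
            F, q, df_den = self._satt_s.f_test(L)
            SS = F * q * self.sigma2_
            rows.append(
                {
                    "term": self._pretty_term(term),
                    "SS": SS,
                    "MS": SS / q,
                    "df_num": q,
                    "df_den": df_den,
                    "F": F,
                    "p": float(stats.f.sf(F, q, df_den)),
                }
            )
        self.anova_ = pd.DataFrame(rows)
        return self

    def _pretty_term(self, term: str) -> str:
        out = term
        for f in self.factors:
            out = out.replace(f"C({f}, Sum)", f)
        return out.replace(":", " x ")

    # -- marginal means and contrasts -----------------------------------------

    def _grid(self) -> pd.DataFrame:
        levels = {f: sorted(self._df[f].unique()) for f in self.factors}
        grid = pd.DataFrame(
            list(itertools.product(*levels.values())), columns=list(self.factors)
        )
        if self.covariate:
            grid[self.covariate] = self._df[self.covariate].mean()
        return grid

    def emmeans(self, factor: str) -> pd.DataFrame:
        """Estimated marginal means: averaged over the other factors at the
        covariate grand mean, with Satterthwaite-df Wald CIs."""
        if factor not in self.factors:
            raise ValueError(f"{factor!r} is not a fixed factor of this model")
        grid = self._grid()
        M = np.asarray(
            patsy.build_design_matrices([self._design_info_t], grid)[0]
        )
        rows = []
        for lev in sorted(self._df[factor].unique()):
            ell = M[(grid[factor] == lev).to_numpy()].mean(axis=0)
            est, se, _, dfree = self._satt_t.t_test(ell)
            tcrit = stats.t.ppf(1 - self.alpha / 2, dfree)
            rows.append(
                {
                    "level": lev,
                    "emmean": est,
                    "se": se,
                    "df": dfree,
                    "ci_low": est - tcrit * se,
                    "ci_high": est + tcrit * se,
                }
            )
        return pd.DataFrame(rows)

    def contrasts(self, factor: str, adjust: str = "bonferroni") -> pd.DataFrame:
        """All pairwise differences of marginal means for one factor.

        p values are Bonferroni-multiplied by the number of pairs (capped
        at 1).  Cohen's d is obtained from the t statistic as
        ``d = 2t/sqrt(df)`` by default, or as estimate divided by the
        total residual SD with ``cohens_d_method='residual'``.
        """
        if factor not in self.factors:
            raise ValueError(f"{factor!r} is not a fixed factor of this model")
        if adjust not in ("bonferroni", "none"):
            raise ValueError("adjust must be 'bonferroni' or 'none'")
        grid = self._grid()
        M = np.asarray(
            patsy.build_design_matrices([self._design_info_t], grid)[0]
        )
        levels = sorted(self._df[factor].unique())
        pairs = list(itertools.combinations(levels, 2))
        mult = len(pairs) if adjust == "bonferroni" else 1
        rows = []
        for a, b in pairs:
            ra = M[(grid[factor] == a).to_numpy()].mean(axis=0)
            rb = M[(grid[factor] == b).to_numpy()].mean(axis=0)
            est, se, t, dfree = self._satt_t.t_test(ra - rb)
            p_raw = 2 * stats.t.sf(abs(t), dfree)
            if self.cohens_d_method == "t2d":
                d = 2.0 * t / np.sqrt(dfree)
            else:
                d = est / np.sqrt(self.sigma2_ + self.tau2_)
            tcrit = stats.t.ppf(1 - self.alpha / 2, dfree)
            rows.append(
                {
                    "pair": f"{a} - {b}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": dfree,
                    "p_raw": p_raw,
                    "p_adjusted": min(1.0, p_raw * mult),
                    "cohens_d": d,
                    "ci_low": est - tcrit * se,
                    "ci_high": est + tcrit * se,
                }
            )
        return pd.DataFrame(rows)

    def to_result(self) -> FitResult:
        return FitResult(
            response=self.response,
            anova=self.anova_,
            coefficients=self.coef_,
            loglik=self.loglik_,
            converged=self.converged_,
            sigma2=self.sigma2_,
            tau2=self.tau2_,
            reference_levels=self._refs(),
            model=self,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_lmm(
    table: pd.DataFrame,
    response: str = "d_prime",
    factors: tuple[str, ...] = ("movement", "session_cue"),
    covariate: str | None = "amplitude_mm",
    group: str = "participant_id",
    **kwargs,
) -> FitResult:
    """Fit the condition LMM and return its F table and coefficients."""
    est = MixedModelAnalysis(
        response=response, factors=factors, covariate=covariate, group=group, **kwargs
    ).fit(table)
    return est.to_result()


def pairwise_contrasts(
    fit: FitResult, factor: str, adjust: str = "bonferroni"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(contrasts, marginal means) for a fixed factor of a fitted model."""
    if fit.model is None:
        raise TactsuppError("FitResult does not carry its fitted model")
    return fit.model.contrasts(factor, adjust=adjust), fit.model.emmeans(factor)


def spearman_family(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    n_tests: int | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlations with a Bonferroni-corrected per-test threshold.

    With the default family of eight correlations per movement parameter
    the per-test threshold is 0.05 / 8 = 0.00625.  Constant inputs yield an
    undefined (NaN) rho with a flag rather than an error.
    """
    n_tests = len(pairs) if n_tests is None else n_tests
    thr = alpha / n_tests
    rows = []
    for i, (x, y) in enumerate(pairs):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise ValueError("each pair needs >= 3 complete observations")
        if np.all(x == x[0]) or np.all(y == y[0]):
            rho, p, undef = np.nan, np.nan, True
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p = stats.spearmanr(x, y)
            undef = not np.isfinite(rho)
        rows.append(
            {
                "label": labels[i] if labels else f"pair_{i + 1}",
                "n": int(x.size),
                "rho": rho,
                "p": p,
                "threshold": thr,
                "significant": bool(np.isfinite(p) and p < thr),
                "undefined": undef,
            }
        )
    return pd.DataFrame(rows)


def paired_t_power(n: int, effect_d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of a paired/one-sample t test via the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = effect_d * np.sqrt(n)
    if tails == 2:
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tc, df, nc))


def required_sample_size(
    effect_d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n for a paired t test to reach the target power.

    Uses the noncentral-t distribution with df = n - 1 and noncentrality
    d*sqrt(n); no normal approximation.  d = 0.5, alpha = 0.05, power = 0.80,
    two-tailed gives n = 34.
    """
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_d <= 0:
        raise ValueError("effect_d must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        if paired_t_power(n, effect_d, alpha, tails) >= power:
            return n
    raise ValueError("target power unreachable within n_max")


def report_tables(fits: dict[str, FitResult]) -> dict:
    """Machine-readable report mirroring the printed F-table layout.

    One entry per response; each term carries SS, MS, dfs (numerator,
    denominator), F and p.
    """
    report = {}
    for name, fit in fits.items():
        report[name] = {
            "converged": fit.converged,
            "loglik": fit.loglik,
            "reference_levels": fit.reference_levels,
            "terms": [
                {
                    "term": r["term"],
                    "SS": r["SS"],
                    "MS": r["MS"],
                    "dfs": [r["df_num"], r["df_den"]],
                    "F": r["F"],
                    "p": r["p"],
                }
                for r in fit.anova.to_dict("records")
            ],
        }
    return report
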