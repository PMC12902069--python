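"""Mixed-effects inference for dyadic synchrony tables.

The model is a linear mixed-effects model with a phase × emotional-context
fixed structure and a random intercept per dyad,

    sync ~ phase * context + (1 | dyad),

estimated by REML. On top of the fit this module provides the inference
pieces the synchrony analysis rests on:

* **Satterthwaite F-tests** per fixed term. For a contrast l the denominator
  df is ``2·f(θ̂)² / (∇f·A·∇f)`` with ``f(θ) = lᵀ Var(β̂; θ) l``, θ the
  variance components and A their asymptotic covariance (inverse REML
  information, obtained numerically). Multi-df terms use the eigenvalue
  decomposition of the contrast covariance and the standard df-combination
  rule, as in lmerTest.
* **Estimated marginal means** per phase and per phase × context cell
  (model-based cell means averaged over the other factor) with Tukey-adjusted
  pairwise phase contrasts via the studentized-range distribution.
* **Variance decomposition**: marginal R² = σ²_f/(σ²_f+σ²_dyad+σ²_res) and
  conditional R² = (σ²_f+σ²_dyad)/(σ²_f+σ²_dyad+σ²_res), with σ²_f the
  variance of the fixed-effect linear predictor over the data (coding
  invariant).

The REML point estimates come from statsmodels' MixedLM; β̂, its covariance
and everything downstream are recomputed here from the closed-form GLS
expressions for the random-intercept covariance, so that all reported
quantities are mutually consistent.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger("dyadsync")

__all__ = [
    "LMMSpec",
    "LMMResult",
    "fit_sync_lmm",
    "r2_mixed",
    "phase_contrasts",
    "descriptive_marginals",
]

_SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class LMMSpec:
    """Model specification for the synchrony mixed model."""

    response: str = "sync_pct"
    fixed: str = "C(phase) * C(context)"
    group: str = "dyad"
    reml: bool = True

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


@dataclass
class LMMResult:
    """Fit summary: estimates, variance components, F-table, EMMs, contrasts, R²."""

    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_dyad: float
    sigma2_resid: float
    singular: bool
    anova: pd.DataFrame  # term, F, num_df, den_df, p
    emm_phase: pd.DataFrame  # phase, emm, se
    emm_cells: pd.DataFrame  # phase, context, emm, se
    contrasts: pd.DataFrame  # pair, estimate, se, df, ci_low, ci_high, p_tukey
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    # internal state for r2_mixed / phase_contrasts recomputation
    _X: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _beta: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Closed-form GLS machinery for the random-intercept covariance
# ---------------------------------------------------------------------------


class _RandomInterceptGLS:
    """Profile-β REML quantities for V = σ²_e I + σ²_d Z Zᵀ, Z a group indicator."""

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray):
        self.X, self.y, self.codes = X, y, codes
        self.n, self.p = X.shape
        self.n_groups = int(codes.max()) + 1
        self.group_sizes = np.bincount(codes, minlength=self.n_groups).astype(float)

    def _woodbury(self, s2d: float, s2e: float):
        """Return XᵀV⁻¹X, XᵀV⁻¹y, yᵀV⁻¹y."""
        X, y, codes = self.X, self.y, self.codes
        gamma = s2d / (s2e + self.group_sizes * s2d)  # per group
        Xs = np.zeros((self.n_groups, self.p))
        np.add.at(Xs, codes, X)
        ys = np.bincount(codes, weights=y, minlength=self.n_groups)
        XtVX = (X.T @ X - (Xs * gamma[:, None]).T @ Xs) / s2e
        XtVy = (X.T @ y - Xs.T @ (gamma * ys)) / s2e
        ytVy = (y @ y - np.sum(gamma * ys**2)) / s2e
        return XtVX, XtVy, ytVy

    def beta_cov(self, s2d: float, s2e: float):
        XtVX, XtVy, _ = self._woodbury(s2d, s2e)
        C = np.linalg.inv(XtVX)
        return C @ XtVy, C

    def reml_loglik(self, s2d: float, s2e: float) -> float:
        s2d, s2e = max(s2d, 0.0), max(s2e, 1e-12)
        XtVX, XtVy, ytVy = self._woodbury(s2d, s2e)
        logdetV = float(
            np.sum((self.group_sizes - 1) * np.log(s2e) + np.log(s2e + self.group_sizes * s2d))
        )
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - XtVy @ beta  # = (y-Xβ̂)ᵀ V⁻¹ (y-Xβ̂)
        return -0.5 * (logdetV + logdetXtVX + quad)

    def theta_cov(self, s2d: float, s2e: float) -> np.ndarray:
        """Asymptotic covariance of (σ²_d, σ²_e): inverse observed REML information."""
        theta = np.array([max(s2d, 0.0), s2e])
        h = np.maximum(1e-4 * np.abs(theta), 1e-7)
        # keep evaluations inside the parameter space
        h[0] = min(h[0], max(theta[0] / 2, 1e-7)) if theta[0] > 0 else 1e-7

        def f(t):
            return self.reml_loglik(max(t[0], 0.0), max(t[1], 1e-12))

        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(theta + ei) - 2 * f(theta) + f(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = (
                        f(theta + ei + ej)
                        - f(theta + ei - ej)
                        - f(theta - ei + ej)
                        + f(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)

    def satterthwaite_df(
        self, l: np.ndarray, s2d: float, s2e: float, A: np.ndarray
    ) -> float:
        """Satterthwaite denominator df for the scalar contrast lᵀβ."""
        if not np.all(np.isfinite(A)):
            return float(self.n - self.p)
        theta = np.array([max(s2d, 0.0), s2e])
        h = np.maximum(1e-5 * np.abs(theta), 1e-8)

        def fvar(t):
            _, C = self.beta_cov(max(t[0], 0.0), max(t[1], 1e-12))
            return float(l @ C @ l)

        g = np.empty(2)
        for i in range(2):
            ei = np.zeros(2)
            ei[i] = h[i]
            g[i] = (fvar(theta + ei) - fvar(np.maximum(theta - ei, [0.0, 1e-12]))) / (
                (theta[i] + h[i]) - max(theta[i] - h[i], 0.0 if i == 0 else 1e-12)
            )
        denom = float(g @ A @ g)
        f0 = fvar(theta)
        if denom <= 0 or f0 <= 0:
            return float(self.n - self.p)
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, 10.0 * self.n))


def _term_f_test(
    gls: _RandomInterceptGLS,
    L: np.ndarray,
    beta: np.ndarray,
    C: np.ndarray,
    s2d: float,
    s2e: float,
    A: np.ndarray,
    singular: bool,
) -> tuple[float, float, float]:
    """F statistic, denominator df, p for the multi-row contrast Lβ = 0."""
    q = L.shape[0]
    M = L @ C @ L.T
    Lb = L @ beta
    try:
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
    except np.linalg.LinAlgError:
        return float("nan"), float("nan"), float("nan")
    if singular:
        ddf = float(gls.n - gls.p)
    else:
        # eigen-orthonormalize the contrast rows; combine per-row Satterthwaite dfs
        vals, vecs = np.linalg.eigh(M)
        keep = vals > max(vals.max(), 0) * 1e-10
        Lp = (vecs[:, keep] / np.sqrt(vals[keep])).T @ L
        nus = np.array(
            [gls.satterthwaite_df(lp, s2d, s2e, A) for lp in Lp]
        )
        good = nus > 2.0
        if not good.any():
            ddf = float(gls.n - gls.p)
        else:
            E = float(np.sum(nus[good] / (nus[good] - 2.0)))
            ddf = 2.0 * E / (E - keep.sum()) if E > keep.sum() else float(gls.n - gls.p)
    p = float(stats.f.sf(F, q, ddf)) if np.isfinite(F) else float("nan")
    return F, ddf, p


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _is_singular(gls: _RandomInterceptGLS, s2d: float, s2e: float) -> bool:
    """Boundary flag: the dyad-intercept variance is treated as zero when it
    is numerically negligible or when the boundary-corrected REML likelihood
    ratio for the random intercept is non-significant at the 5% level
    (critical value 2.706 for the 0.5·χ²₀ + 0.5·χ²₁ mixture)."""
    if s2d <= _SINGULAR_TOL * (s2d + s2e):
        return True
    beta_ols, _ = gls.beta_cov(0.0, 1.0)
    rss = float(np.sum((gls.y - gls.X @ beta_ols) ** 2))
    s2e0 = rss / (gls.n - gls.p)
    lrt = 2.0 * (gls.reml_loglik(s2d, s2e) - gls.reml_loglik(0.0, s2e0))
    return lrt < 2.706


def _estimate_components(
    spec: LMMSpec, data: pd.DataFrame, codes: np.ndarray, gls: _RandomInterceptGLS
) -> tuple[float, float]:
    """REML variance-component estimates (σ²_dyad, σ²_res).

    statsmodels' MixedLM optimiser is tried first; if it fails to converge
    (its L-BFGS path can hit singular working matrices on some responses),
    the closed-form REML log-likelihood for the random-intercept structure is
    maximised directly on the log-variance scale.
    """
    for method in ("lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(spec.formula, data, groups=codes)
                fit = model.fit(reml=spec.reml, method=method)
            s2e = float(fit.scale)
            s2d = float(np.asarray(fit.cov_re)[0, 0])
            if np.isfinite(s2e) and s2e > 0 and np.isfinite(s2d) and s2d >= 0:
                return s2d, s2e
        except (np.linalg.LinAlgError, ValueError):
            continue
    logger.info("MixedLM optimiser failed; maximising the REML likelihood directly")
    from scipy.optimize import minimize

    s2_tot = float(np.var(gls.y))

    def neg(params):
        return -gls.reml_loglik(np.exp(params[0]), np.exp(params[1]))

    best = None
    for frac in (0.5, 0.1, 0.9):
        start = np.log([max(s2_tot * frac, 1e-8), max(s2_tot * (1 - frac), 1e-8)])
        res = minimize(neg, start, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    s2d, s2e = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    return (0.0 if s2d < 1e-10 * (s2d + s2e) else s2d), s2e


def fit_sync_lmm(table: pd.DataFrame, spec: LMMSpec = LMMSpec()) -> LMMResult:
    """Fit the random-intercept mixed model and assemble the full inference
    report (F-table, EMMs, Tukey phase contrasts, R²).

    Rows with a missing response (e.g. zero-reference-event phases) are
    dropped listwise. A fit whose dyad-intercept variance collapses to zero
    is returned with ``singular=True`` (fixed effects then equal OLS), not
    raised.
    """
    data = table.dropna(subset=[spec.response]).copy()
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least 2 groups (dyads) to fit the mixed model")
    y_df, X_df = patsy.dmatrices(spec.formula, data, return_type="dataframe")
    design_info = X_df.design_info
    X = np.asarray(X_df, dtype=float)
    y = np.asarray(y_df, dtype=float).ravel()
    codes, _ = pd.factorize(data[spec.group], sort=True)
    gls = _RandomInterceptGLS(X, y, codes)

    if np.var(y) < 1e-300:
        # degenerate all-equal response: define the zero-variance limit
        beta = np.zeros(X.shape[1])
        beta[0] = y[0] if len(y) else 0.0
        s2d = s2e = 0.0
        singular = True
        C = np.zeros((X.shape[1], X.shape[1]))
        A = np.full((2, 2), np.nan)
    else:
        s2d, s2e = _estimate_components(spec, data, codes, gls)
        singular = _is_singular(gls, s2d, s2e)
        if singular:
            logger.warning(
                "singular fit: no detectable dyad-intercept variance; "
                "reporting the boundary (OLS) solution"
            )
            s2d = 0.0
            # REML residual variance at the boundary
            beta_ols, _ = gls.beta_cov(0.0, 1.0)
            rss = float(np.sum((y - X @ beta_ols) ** 2))
            s2e = rss / (gls.n - gls.p)
        beta, C = gls.beta_cov(s2d, s2e)
        A = gls.theta_cov(s2d, s2e) if not singular else np.full((2, 2), np.nan)

    names = design_info.column_names
    params = pd.Series(beta, index=names)
    covp = pd.DataFrame(C, index=names, columns=names)

    # estimated marginal means over the phase x context grid
    phases = sorted(data["phase"].unique())
    contexts = sorted(data["context"].unique())
    grid = pd.DataFrame(
        [{"phase": ph, "context": ctx} for ph, ctx in itertools.product(phases, contexts)]
    )
    (X_grid,) = patsy.build_design_matrices([design_info], grid)
    X_grid = np.asarray(X_grid, dtype=float)
    cell_emm = X_grid @ beta
    cell_se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X_grid, C, X_grid), 0.0))
    emm_cells = grid.assign(emm=cell_emm, se=cell_se)
    rows_phase = []
    phase_l: dict[str, np.ndarray] = {}
    for ph in phases:
        sel = (grid["phase"] == ph).to_numpy()
        l = X_grid[sel].mean(axis=0)
        phase_l[ph] = l
        rows_phase.append(
            {"phase": ph, "emm": float(l @ beta), "se": float(np.sqrt(max(l @ C @ l, 0.0)))}
        )
    emm_phase = pd.DataFrame(rows_phase)
    context_l: dict[str, np.ndarray] = {}
    for ctx in contexts:
        sel = (grid["context"] == ctx).to_numpy()
        context_l[ctx] = X_grid[sel].mean(axis=0)

    # F-table: main effects as marginal (EMM) contrasts averaged over the
    # other factor — the Type-III tests a mixed-model ANOVA reports — and the
    # interaction as its coefficient block.
    term_L: dict[str, np.ndarray] = {}
    if len(phases) > 1:
        term_L["phase"] = np.vstack([phase_l[p] - phase_l[phases[0]] for p in phases[1:]])
    if len(contexts) > 1:
        term_L["context"] = np.vstack(
            [context_l[c] - context_l[contexts[0]] for c in contexts[1:]]
        )
    inter = [t for t in design_info.term_name_slices if ":" in t]
    if inter:
        sl = design_info.term_name_slices[inter[0]]
        q = sl.stop - sl.start
        L = np.zeros((q, X.shape[1]))
        L[np.arange(q), np.arange(sl.start, sl.stop)] = 1.0
        term_L["phase:context"] = L
    anova_rows = []
    zero_var = s2d + s2e == 0.0
    for term, L in term_L.items():
        if zero_var:
            F, ddf, p = 0.0, float(gls.n - gls.p), 1.0
        else:
            F, ddf, p = _term_f_test(gls, L, beta, C, s2d, s2e, A, singular)
        anova_rows.append(
            {"term": term, "F": F, "num_df": L.shape[0], "den_df": ddf, "p": p}
        )
    anova = pd.DataFrame(anova_rows)

    result = LMMResult(
        params=params,
        cov_params=covp,
        sigma2_dyad=s2d,
        sigma2_resid=s2e,
        singular=singular,
        anova=anova,
        emm_phase=emm_phase,
        emm_cells=emm_cells,
        contrasts=pd.DataFrame(),
        r2_marginal=float("nan"),
        r2_conditional=float("nan"),
        n_obs=gls.n,
        n_groups=gls.n_groups,
        _X=X,
        _beta=beta,
    )
    result.contrasts = _phase_contrast_table(gls, phase_l, beta, C, s2d, s2e, A, singular)
    try:
        result.r2_marginal, result.r2_conditional = r2_mixed(result)
    except ValueError:  # zero total variance (all-equal response)
        result.r2_marginal = result.r2_conditional = float("nan")
    return result


def _phase_contrast_table(gls, phase_l, beta, C, s2d, s2e, A, singular) -> pd.DataFrame:
    phases = list(phase_l)
    k = len(phases)
    rows = []
    for p1, p2 in itertools.combinations(phases, 2):
        l = phase_l[p1] - phase_l[p2]
        est = float(l @ beta)
        se = float(np.sqrt(max(l @ C @ l, 0.0)))
        if se == 0.0:
            rows.append(
                {"pair": f"{p1} - {p2}", "estimate": est, "se": 0.0, "df": float(gls.n - gls.p),
                 "ci_low": est, "ci_high": est, "p_tukey": 1.0}
            )
            continue
        df = (
            float(gls.n - gls.p)
            if singular or not np.all(np.isfinite(A))
            else gls.satterthwaite_df(l, s2d, s2e, A)
        )
        tstat = est / se
        if k >= 2:
            p_tukey = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, df))
            qcrit = float(stats.studentized_range.ppf(0.95, k, df)) / np.sqrt(2.0)
        else:  # single level: no contrast family
            p_tukey, qcrit = float("nan"), float("nan")
        rows.append(
            {
                "pair": f"{p1} - {p2}",
                "estimate": est,
                "se": se,
                "df": df,
                "ci_low": est - qcrit * se,
                "ci_high": est + qcrit * se,
                "p_tukey": p_tukey,
            }
        )
    return pd.DataFrame(rows)


def phase_contrasts(result: LMMResult) -> pd.DataFrame:
    """All pairwise phase differences of estimated marginal means with 95%
    Tukey confidence intervals and adjusted p-values."""
    return result.contrasts


def r2_mixed(result: LMMResult) -> tuple[float, float]:
    """Marginal and conditional R² of a fitted random-intercept model.

    σ²_f is the population variance of the fixed-effect linear predictor over
    the modelled rows; the decomposition is over σ²_f + σ²_dyad + σ²_res.
    Raises ``ValueError`` when the total variance is zero.
    """
    s2f = float(np.var(result._X @ result._beta))
    total = s2f + result.sigma2_dyad + result.sigma2_resid
    if total <= 0:
        raise ValueError("zero total variance: R² undefined")
    return s2f / total, (s2f + result.sigma2_dyad) / total


def descriptive_marginals(
    table: pd.DataFrame, measure: str, by: list[str]
) -> pd.DataFrame:
    """Mean, SD and n per cell of a long-format metrics table.

    Single-observation cells report a missing SD; empty cells (after NaN
    removal) are absent from the output with a warning.
    """
    sub = table[table["measure"] == measure]
    if sub.empty:
        logger.warning("no rows for measure %r", measure)
        return pd.DataFrame(columns=by + ["mean", "sd", "n"])
    sub = sub.dropna(subset=["value"])
    out = (
        sub.groupby(by, observed=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out
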