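"""Gamma mixed model for the duration of long-range movements.

Each long-range movement (LRM) track contributes one record: its
duration in hours (positive response), the median solar radiation over
its fixes and the individual's age at track start (both z-scored), and
the release cohort.  The model is a Gamma GLMM with log link::

    duration_ij ~ Gamma(shape nu, mean mu_ij)
    log mu_ij = x_ij' beta + b_i,      b_i ~ N(0, sigma_b^2)

fitted by Laplace-approximated maximum likelihood: the per-individual
random-intercept modes are found by an inner (per-group, independent)
Newton iteration, and the outer parameters (beta, log nu, log sigma_b)
maximise the Laplace log-likelihood by Nelder-Mead with a BFGS polish.
Stepwise-forward selection by likelihood-ratio testing adds terms from
the pool {radiation, age, cohort, random intercept, radiation x age}
while the entry p-value is below 0.05, interaction considered only once
both main effects are present.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

TERM_POOL = ("median_radiation_z", "age_z", "cohort", "random_intercept",
             "radiation_x_age")


@dataclass
class DurationGlmmFit:
    terms: tuple[str, ...]
    beta: np.ndarray
    beta_names: tuple[str, ...]
    shape: float
    sigma_b: float
    random_modes: np.ndarray
    group_levels: np.ndarray
    loglik: float
    aic: float
    converged: bool
    has_random: bool
    zscore_stats: dict = field(default_factory=dict)

    def fitted_mean(self, X: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
        eta = X @ self.beta
        if self.has_random and groups is not None:
            lookup = {g: b for g, b in zip(self.group_levels, self.random_modes)}
            eta = eta + np.array([lookup.get(g, 0.0) for g in groups])
        return np.exp(eta)


def build_lrm_table(
    track_table: pd.DataFrame,
    annotated_fixes: pd.DataFrame,
    individuals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One record per complete LRM track with z-scored covariates.

    ``track_table`` must carry per-fix membership via ``individual_id``
    and start/end times; the median radiation is taken over the track's
    own fixes in ``annotated_fixes``.  ``individuals`` optionally maps
    ``individual_id`` to ``birth_date`` and ``cohort``; ages are in
    years at track start.  Z-scoring uses the LRM-table mean/SD, which
    are stored in ``attrs`` for back-transformation.
    """
    lrm = track_table[(track_table["label"] == "LRM") & track_table["complete"]].copy()
    if lrm.empty:
        raise ValueError("no complete LRM tracks; cannot build the duration table")
    n_censored = int(((track_table["label"] == "LRM") & ~track_table["complete"]).sum())
    if n_censored:
        logger.info("excluded %d truncated LRM tracks (censored durations)", n_censored)
    # a single-fix track has no measurable elapsed duration
    n_zero = int((lrm["duration_h"] <= 0).sum())
    if n_zero:
        logger.info("excluded %d LRM tracks with unmeasurable (zero) duration", n_zero)
        lrm = lrm[lrm["duration_h"] > 0]
    if lrm.empty:
        raise ValueError("no LRM tracks with positive duration")

    fixes = annotated_fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    med_rad = []
    for _, row in lrm.iterrows():
        sel = fixes[
            (fixes["individual_id"] == row["individual_id"])
            & (fixes["timestamp"] >= pd.Timestamp(row["start"]))
            & (fixes["timestamp"] <= pd.Timestamp(row["end"]))
        ]
        med_rad.append(float(np.nanmedian(sel["radiation_wm2"])) if len(sel) else np.nan)
    lrm["median_radiation"] = med_rad

    if individuals is not None:
        info = individuals.set_index("individual_id")
        lrm["cohort"] = lrm["individual_id"].map(info["cohort"]).astype(str)
        birth = pd.to_datetime(lrm["individual_id"].map(info["birth_date"]), utc=True)
        start = pd.to_datetime(lrm["start"], utc=True)
        lrm["age_years"] = (start - birth).dt.total_seconds() / (365.25 * 24 * 3600)
    else:
        lrm["cohort"] = "c1"
        lrm["age_years"] = 1.0

    out = lrm[["track_id", "individual_id", "duration_h", "median_radiation",
               "age_years", "cohort"]].reset_index(drop=True)
    stats = {}
    for src, dst in (("median_radiation", "median_radiation_z"),
                     ("age_years", "age_z")):
        mu = float(np.nanmean(out[src]))
        sd = float(np.nanstd(out[src]))
        sd = sd if sd > 0 else 1.0
        out[dst] = (out[src] - mu) / sd
        stats[dst] = (mu, sd)
    out.attrs["zscore_stats"] = stats
    return out


def _design(table: pd.DataFrame, terms: tuple[str, ...]):
    cols = [np.ones(len(table))]
    names = ["intercept"]
    if "median_radiation_z" in terms:
        cols.append(table["median_radiation_z"].to_numpy(float))
        names.append("median_radiation_z")
    if "age_z" in terms:
        cols.append(table["age_z"].to_numpy(float))
        names.append("age_z")
    if "cohort" in terms:
        levels = sorted(table["cohort"].astype(str).unique())
        for lev in levels[1:]:
            cols.append((table["cohort"].astype(str) == lev).to_numpy(float))
            names.append(f"cohort[{lev}]")
    if "radiation_x_age" in terms:
        cols.append((table["median_radiation_z"] * table["age_z"]).to_numpy(float))
        names.append("radiation_x_age")
    return np.column_stack(cols), tuple(names)


def _gamma_loglik(y, mu, nu):
    return (nu * np.log(nu) - nu * np.log(mu) + (nu - 1.0) * np.log(y)
            - nu * y / mu - gammaln(nu))


def _laplace_loglik(y, X, group_idx, n_groups, beta, log_nu, log_sb,
                    return_modes: bool = False):
    """Laplace-approximate marginal log-likelihood (vectorised over groups)."""
    nu = np.exp(log_nu)
    sb2 = np.exp(2.0 * log_sb)
    eta0 = X @ beta
    b = np.zeros(n_groups)
    for _ in range(50):
        mu = np.exp(eta0 + b[group_idx])
        r = nu * (y / mu - 1.0)                      # d loglik / d b per obs
        g = np.bincount(group_idx, r, n_groups) - b / sb2
        h = np.bincount(group_idx, nu * y / mu, n_groups) + 1.0 / sb2
        step = g / h
        # dampen to keep the inner iteration stable for extreme starts
        step = np.clip(step, -5.0, 5.0)
        b_new = b + step
        if np.max(np.abs(b_new - b)) < 1e-10:
            b = b_new
            break
        b = b_new
    mu = np.exp(eta0 + b[group_idx])
    ll_data = _gamma_loglik(y, mu, nu).sum()
    h = np.bincount(group_idx, nu * y / mu, n_groups) + 1.0 / sb2
    ll = (ll_data - 0.5 * np.sum(b**2) / sb2
          - 0.5 * n_groups * np.log(sb2) - 0.5 * np.sum(np.log(h)))
    if return_modes:
        return float(ll), b
    return float(ll)


def _gamma_glm_fit(y, X, max_iter: int = 100):
    """Plain Gamma GLM (log link) by Newton scoring, plus shape MLE."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean())
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        z = y / mu - 1.0
        g = X.T @ z
        Winfo = (X * (y / mu)[:, None]).T @ X
        try:
            step = np.linalg.solve(Winfo + 1e-10 * np.eye(X.shape[1]), g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(X @ beta)

    def neg_prof(log_nu):
        return -_gamma_loglik(y, mu, np.exp(log_nu)).sum()

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_prof, bounds=(-4, 8), method="bounded")
    return beta, float(np.exp(res.x)), float(-res.fun)


def fit_gamma_glmm(
    table: pd.DataFrame,
    terms: tuple[str, ...] = ("median_radiation_z", "random_intercept"),
    response: str = "duration_h",
    group: str = "individual_id",
    min_rows: int = 10,
) -> DurationGlmmFit:
    """Fit the Gamma GLMM (or GLM when no random intercept is requested)."""
    y = table[response].to_numpy(dtype=float)
    if len(y) < min_rows:
        raise ValueError(f"need at least {min_rows} rows, have {len(y)}")
    if np.any(y <= 0):
        raise ValueError("durations must be positive")
    fixed_terms = tuple(t for t in terms if t != "random_intercept")
    has_random = "random_intercept" in terms
    X, names = _design(table, fixed_terms)

    levels, group_idx = np.unique(table[group].astype(str), return_inverse=True)
    if has_random and len(levels) < 2:
        warnings.warn("single individual: dropping the random intercept")
        has_random = False

    beta0, nu0, ll_glm = _gamma_glm_fit(y, X)
    if not has_random:
        k = X.shape[1] + 1
        return DurationGlmmFit(terms=tuple(terms), beta=beta0, beta_names=names,
                               shape=nu0, sigma_b=0.0,
                               random_modes=np.zeros(len(levels)),
                               group_levels=levels, loglik=ll_glm,
                               aic=-2 * ll_glm + 2 * k, converged=True,
                               has_random=False)

    n_groups = len(levels)

    def negll(params):
        beta = params[:-2]
        val = _laplace_loglik(y, X, group_idx, n_groups, beta,
                              params[-2], params[-1])
        return -val if np.isfinite(val) else 1e12

    x0 = np.concatenate([beta0, [np.log(nu0), np.log(0.3)]])
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
    res2 = minimize(negll, res.x, method="BFGS",
                    options={"maxiter": 200, "gtol": 1e-7})
    best = res2 if res2.fun <= res.fun else res
    beta = best.x[:-2]
    log_nu, log_sb = best.x[-2], best.x[-1]
    ll, modes = _laplace_loglik(y, X, group_idx, n_groups, beta, log_nu, log_sb,
                                return_modes=True)
    k = X.shape[1] + 2  # + shape + sigma_b
    converged = bool(res.success or res2.success)
    if not converged:
        warnings.warn("Gamma GLMM optimiser did not report convergence")
    return DurationGlmmFit(terms=tuple(terms), beta=beta, beta_names=names,
                           shape=float(np.exp(log_nu)),
                           sigma_b=float(np.exp(log_sb)), random_modes=modes,
                           group_levels=levels, loglik=float(ll),
                           aic=-2 * float(ll) + 2 * k, converged=converged,
                           has_random=True)


def stepwise_forward(
    table: pd.DataFrame,
    term_pool: tuple[str, ...] = TERM_POOL,
    alpha: float = 0.05,
    response: str = "duration_h",
    group: str = "individual_id",
) -> tuple[DurationGlmmFit, pd.DataFrame]:
    """Forward selection by likelihood-ratio testing.

    Starting from the intercept-only Gamma GLM, at each step the
    candidate term with the smallest LRT p-value below ``alpha`` enters;
    the radiation x age interaction is eligible only once both main
    effects are in the model.  Returns the selected fit and a
    step-by-step table (AIC, chi-squared, df, p per candidate tried).
    """
    current: tuple[str, ...] = ()
    current_fit = fit_gamma_glmm(table, current, response, group)
    rows = [{"step": 0, "model": "intercept", "added": "", "aic": current_fit.aic,
             "loglik": current_fit.loglik, "chi2": np.nan, "df": np.nan,
             "p": np.nan, "selected": True}]
    step = 0
    remaining = list(term_pool)
    while remaining:
        step += 1
        best = None
        for term in remaining:
            if term == "radiation_x_age" and not (
                "median_radiation_z" in current and "age_z" in current
            ):
                continue
            cand = current + (term,)
            fit = fit_gamma_glmm(table, cand, response, group)
            df = _df_added(table, current, cand)
            stat = max(2.0 * (fit.loglik - current_fit.loglik), 0.0)
            p = float(chi2.sf(stat, df))
            rows.append({"step": step, "model": "+".join(cand) or "intercept",
                         "added": term, "aic": fit.aic, "loglik": fit.loglik,
                         "chi2": stat, "df": df, "p": p, "selected": False})
            if p < alpha and (best is None or p < best[0]):
                best = (p, term, fit)
        if best is None:
            break
        _, term, fit = best
        current = current + (term,)
        current_fit = fit
        remaining.remove(term)
        for r in rows:
            if r["step"] == step and r["added"] == term:
                r["selected"] = True
    return current_fit, pd.DataFrame(rows)


def _df_added(table, small: tuple[str, ...], large: tuple[str, ...]) -> int:
    Xs, _ = _design(table, tuple(t for t in small if t != "random_intercept"))
    Xl, _ = _design(table, tuple(t for t in large if t != "random_intercept"))
    df = Xl.shape[1] - Xs.shape[1]
    if ("random_intercept" in large) != ("random_intercept" in small):
        df += 1
    return max(df, 1)


def residual_diagnostics(fit: DurationGlmmFit, table: pd.DataFrame,
                         response: str = "duration_h",
                         group: str = "individual_id") -> dict:
    """Gamma deviance residuals and simple trend summaries."""
    y = table[response].to_numpy(dtype=float)
    X, _ = _design(table, tuple(t for t in fit.terms if t != "random_intercept"))
    mu = fit.fitted_mean(X, table[group].astype(str).to_numpy())
    dev = 2.0 * (-np.log(np.maximum(y / mu, 1e-300)) + (y - mu) / mu)
    resid = np.sign(y - mu) * np.sqrt(np.maximum(dev, 0.0))
    out = {"residuals": resid, "fitted": mu, "mean_residual": float(resid.mean())}
    for col in ("median_radiation_z", "age_z"):
        if col in table.columns:
            x = table[col].to_numpy(float)
            if np.std(x) > 0:
                out[f"slope_vs_{col}"] = float(np.polyfit(x, resid, 1)[0])
    out["slope_vs_fitted"] = float(np.polyfit(mu, resid, 1)[0]) if np.std(mu) > 0 else 0.0
    return out
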