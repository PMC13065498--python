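"""Ordered-categorical (cumulative-logit) additive mixed model.

The response is the movement type of each GPS fix, ordered
SRM < MRM < LRM.  A latent logistic variable with additive predictor
``eta`` drives the category probabilities through two thresholds::

    P(y <= k | x) = sigmoid(theta_k - eta(x)),    theta_1 < theta_2

``eta`` is the sum of an intercept, parametric effects (sex, release
cohort), penalized smooths (cyclic splines for wind direction, day of
year and elapsed time since release; curvature-penalized cubic splines
for solar radiation and wind strength; a direction x strength tensor
product; optional per-sex age smooths) and i.i.d. Gaussian random
intercepts per individual, handled as a ridge-penalized block.

``theta_1`` is fixed at -1 for identifiability (the model has a free
intercept; any anchored cut point is equivalent up to shift) and
``theta_2`` is estimated.  Fitting maximises the penalized log-likelihood
by Newton iteration with step halving; smoothing parameters are chosen
by coordinate-wise grid search on the AIC, where model dimension is the
trace-based effective degrees of freedom (EDF).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import smooths

logger = logging.getLogger(__name__)

THETA1 = -1.0
CATEGORIES = ("SRM", "MRM", "LRM")


@dataclass
class Term:
    """One additive term of the linear predictor.

    ``kind`` is one of ``linear``, ``factor``, ``cyclic``, ``spline``,
    ``tensor`` (cyclic x spline) or ``random`` (random intercept).
    ``by`` names a factor column splitting a smooth into per-level
    copies (used for the per-sex age smooths).
    """

    kind: str
    columns: tuple[str, ...]
    k: int | tuple[int, int] = 8
    period: float | None = None
    by: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"{self.kind}({','.join(self.columns)})"
        if self.kind in ("cyclic", "spline", "tensor"):
            ks = self.k if isinstance(self.k, tuple) else (self.k,)
            if any(kk < 4 for kk in ks):
                raise ValueError("basis sizes must be >= 4")


@dataclass
class OrdinalGamSpec:
    terms: list[Term] = field(default_factory=list)

    @staticmethod
    def default() -> "OrdinalGamSpec":
        return OrdinalGamSpec(
            terms=[
                Term("cyclic", ("wind_dir_deg",), k=8, period=360.0, name="f(dir)"),
                Term("spline", ("wind_kmh",), k=6, name="f(wind)"),
                Term("spline", ("radiation_wm2",), k=6, name="f(rad)"),
                Term("cyclic", ("doy",), k=6, period=365.25, name="f(doy)"),
                Term("tensor", ("wind_dir_deg", "wind_kmh"), k=(8, 5),
                     period=360.0, name="te(dir,wind)"),
                Term("random", ("individual_id",), name="b(individual)"),
            ]
        )


@dataclass
class _Block:
    term: Term
    sl: slice
    design: np.ndarray
    penalties: list[np.ndarray]
    lambda_idx: list[int]
    predictor: object


@dataclass
class OrdinalGamFit:
    spec: OrdinalGamSpec
    beta: np.ndarray
    theta2: float
    lambdas: np.ndarray
    blocks: list[_Block]
    loglik: float
    penalized_loglik: float
    edf_total: float
    edf_by_term: dict[str, float]
    aic: float
    converged: bool
    iterations: int
    cov: np.ndarray | None = None       # (p+1, p+1) incl. theta2
    reference: dict | None = None

    @property
    def theta1(self) -> float:
        return THETA1


def _encode_response(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "iuf":
        out = arr.astype(int)
    else:
        mapping = {c: i + 1 for i, c in enumerate(CATEGORIES)}
        out = np.array([mapping[v] for v in arr], dtype=int)
    if not np.isin(out, (1, 2, 3)).all():
        raise ValueError("response categories must be SRM/MRM/LRM (1/2/3)")
    return out


def _build_blocks(spec: OrdinalGamSpec, data: pd.DataFrame):
    """Assemble the full design matrix and penalty bookkeeping."""
    blocks: list[_Block] = []
    cols: list[np.ndarray] = [np.ones((len(data), 1))]
    start = 1
    lam_count = 0
    for term in spec.terms:
        sub_designs: list[tuple[np.ndarray, list[np.ndarray], object, int]] = []
        if term.kind == "linear":
            x = data[term.columns[0]].to_numpy(dtype=float)[:, None]
            col = term.columns[0]
            sub_designs.append((x, [], (lambda d, c=col: d[c].to_numpy(float)[:, None]), 0))
        elif term.kind == "factor":
            col = term.columns[0]
            levels = np.array(sorted(pd.unique(data[col].astype(str))))
            if len(levels) < 2:
                raise ValueError(f"factor {col!r} needs >= 2 levels")
            ref = levels[0]

            def fac(d, c=col, lv=levels[1:]):
                v = d[c].astype(str).to_numpy()
                return np.column_stack([(v == l).astype(float) for l in lv])

            sub_designs.append((fac(data), [], fac, 0))
        elif term.kind == "random":
            col = term.columns[0]
            levels = np.array(sorted(pd.unique(data[col].astype(str))))

            def ran(d, c=col, lv=levels):
                v = d[c].astype(str).to_numpy()
                out = np.zeros((len(v), len(lv)))
                for j, l in enumerate(lv):
                    out[v == l, j] = 1.0
                return out

            X = ran(data)
            sub_designs.append((X, [np.eye(X.shape[1])], ran, 0))
        elif term.kind in ("cyclic", "spline"):
            x = data[term.columns[0]].to_numpy(dtype=float)
            if term.kind == "cyclic":
                X, S, ev = smooths.cyclic_basis(x, int(term.k), float(term.period))
                nulld = 0  # constant removed by constraint; cyclic null space = const
            else:
                X, S, ev = smooths.crs_basis(x, int(term.k))
                nulld = 1  # after constraint: the linear function remains unpenalized
            Xc, Ss, Z = smooths.sum_to_zero(X, [S])

            def smooth_pred(d, c=term.columns[0], ev=ev, Z=Z):
                return ev(d[c].to_numpy(float)) @ Z

            sub_designs.append((Xc, Ss, smooth_pred, nulld))
        elif term.kind == "tensor":
            ka, kb = term.k
            xa = data[term.columns[0]].to_numpy(dtype=float)
            xb = data[term.columns[1]].to_numpy(dtype=float)
            Xa, Sa, eva = smooths.cyclic_basis(xa, ka, float(term.period))
            Xb, Sb, evb = smooths.crs_basis(xb, kb)
            X = smooths.tensor_design(Xa, Xb)
            pens = smooths.tensor_penalties(Sa, Sb, Xa.shape[1], Xb.shape[1])
            Xc, Ss, Z = smooths.sum_to_zero(X, pens)

            def te_pred(d, ca=term.columns[0], cb=term.columns[1],
                        eva=eva, evb=evb, Z=Z):
                return smooths.tensor_design(
                    eva(d[ca].to_numpy(float)), evb(d[cb].to_numpy(float))) @ Z

            sub_designs.append((Xc, Ss, te_pred, 1))
        else:
            raise ValueError(f"unknown term kind {term.kind!r}")

        for X, Ss, predictor, nulld in sub_designs:
            if term.by is not None:
                byv = data[term.by].astype(str).to_numpy()
                levels = sorted(pd.unique(byv))
                for lev in levels:
                    mask = (byv == lev).astype(float)[:, None]
                    Xl = X * mask

                    def by_pred(d, p=predictor, b=term.by, l=lev):
                        m = (d[b].astype(str).to_numpy() == l).astype(float)[:, None]
                        return p(d) * m

                    sl = slice(start, start + Xl.shape[1])
                    lam_idx = list(range(lam_count, lam_count + len(Ss)))
                    lam_count += len(Ss)
                    t = Term(term.kind, term.columns, term.k, term.period,
                             term.by, name=f"{term.name}[{lev}]")
                    blocks.append(_Block(t, sl, Xl, Ss, lam_idx, by_pred))
                    cols.append(Xl)
                    start = sl.stop
            else:
                sl = slice(start, start + X.shape[1])
                lam_idx = list(range(lam_count, lam_count + len(Ss)))
                lam_count += len(Ss)
                blocks.append(_Block(term, sl, X, Ss, lam_idx, predictor))
                cols.append(X)
                start = sl.stop
    return np.hstack(cols), blocks, lam_count


def _cumlogit_derivs(y: np.ndarray, eta: np.ndarray, theta2: float):
    """Log-likelihood and first/second derivatives wrt (eta, theta2)."""
    z1 = THETA1 - eta
    z2 = theta2 - eta
    F1, F2 = expit(z1), expit(z2)
    f1 = F1 * (1.0 - F1)
    f2 = F2 * (1.0 - F2)
    tiny = 1e-12

    ll = np.empty_like(eta)
    d_eta = np.empty_like(eta)
    d_th = np.zeros_like(eta)
    h_ee = np.empty_like(eta)
    h_et = np.zeros_like(eta)
    h_tt = np.zeros_like(eta)

    m1 = y == 1
    m2 = y == 2
    m3 = y == 3

    ll[m1] = np.log(np.maximum(F1[m1], tiny))
    d_eta[m1] = F1[m1] - 1.0
    h_ee[m1] = -f1[m1]

    P2 = np.maximum(F2 - F1, tiny)
    ll[m2] = np.log(P2[m2])
    d_eta[m2] = (f1[m2] - f2[m2]) / P2[m2]
    d_th[m2] = f2[m2] / P2[m2]
    df1 = -f1 * (1.0 - 2.0 * F1)   # d f1 / d eta
    df2 = -f2 * (1.0 - 2.0 * F2)
    h_ee[m2] = ((df1[m2] - df2[m2]) * P2[m2] - (f1[m2] - f2[m2]) ** 2) / P2[m2] ** 2
    h_et[m2] = (df2[m2] * P2[m2] - f2[m2] * (f1[m2] - f2[m2])) / P2[m2] ** 2
    h_tt[m2] = (f2[m2] * (1.0 - 2.0 * F2[m2]) * P2[m2] - f2[m2] ** 2) / P2[m2] ** 2

    P3 = np.maximum(1.0 - F2, tiny)
    ll[m3] = np.log(P3[m3])
    d_eta[m3] = F2[m3]
    d_th[m3] = -F2[m3]
    h_ee[m3] = -f2[m3]
    h_et[m3] = f2[m3]
    h_tt[m3] = -f2[m3]
    return ll, d_eta, d_th, h_ee, h_et, h_tt


def category_probs(eta: np.ndarray, theta2: float) -> np.ndarray:
    """(n, 3) category probabilities at the given linear predictor."""
    F1 = expit(THETA1 - np.asarray(eta, dtype=float))
    F2 = expit(theta2 - np.asarray(eta, dtype=float))
    return np.column_stack([F1, F2 - F1, 1.0 - F2])


def _penalty_matrix(blocks, lambdas, p) -> np.ndarray:
    P = np.zeros((p, p))
    for blk in blocks:
        for S, li in zip(blk.penalties, blk.lambda_idx):
            P[blk.sl, blk.sl] += lambdas[li] * S
    return P


def _fit_inner(
    X: np.ndarray,
    y: np.ndarray,
    blocks,
    lambdas: np.ndarray,
    weights: np.ndarray,
    beta0=None,
    theta20=1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
):
    """Penalized Newton with step halving at fixed smoothing parameters."""
    n, p = X.shape
    P = _penalty_matrix(blocks, lambdas, p)
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    theta2 = float(theta20)

    def objective(b, t2):
        ll = _cumlogit_derivs(y, X @ b, t2)[0]
        return float(weights @ ll) - 0.5 * b @ P @ b

    obj = objective(beta, theta2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        _, d_eta, d_th, h_ee, h_et, h_tt = _cumlogit_derivs(y, eta, theta2)
        g_beta = X.T @ (weights * d_eta) - P @ beta
        g_th = float(weights @ d_th)
        Wee = weights * h_ee
        H = np.empty((p + 1, p + 1))
        H[:p, :p] = (X * Wee[:, None]).T @ X - P
        cross = X.T @ (weights * h_et)
        H[:p, p] = cross
        H[p, :p] = cross
        H[p, p] = float(weights @ h_tt)
        g = np.concatenate([g_beta, [g_th]])
        try:
            step = np.linalg.solve(-H + 1e-10 * np.eye(p + 1), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        # step halving: accept only non-decreasing penalized log-likelihood
        scale = 1.0
        for _ in range(30):
            nb = beta + scale * step[:p]
            nt = theta2 + scale * step[p]
            if nt > THETA1 + 1e-6:
                nobj = objective(nb, nt)
                if nobj >= obj - 1e-12:
                    break
            scale *= 0.5
        else:
            converged = True  # no improving step: at a (numerical) optimum
            break
        beta, theta2 = nb, nt
        if abs(nobj - obj) <= tol * (abs(obj) + 1e-10):
            obj = nobj
            converged = True
            break
        obj = nobj
    ll = float(weights @ _cumlogit_derivs(y, X @ beta, theta2)[0])
    return beta, theta2, obj, ll, converged, it


def _edf(X, y, beta, theta2, blocks, lambdas, weights):
    """Trace-based EDF per block: tr[(H_u + P)^-1 H_u] restricted to block."""
    p = X.shape[1]
    _, _, _, h_ee, _, _ = _cumlogit_derivs(y, X @ beta, theta2)
    W = -(weights * h_ee)
    XtWX = (X * W[:, None]).T @ X
    P = _penalty_matrix(blocks, lambdas, p)
    A = np.linalg.solve(XtWX + P + 1e-10 * np.eye(p), XtWX)
    per_term: dict[str, float] = {}
    for blk in blocks:
        per_term[blk.term.name] = float(np.trace(A[blk.sl, blk.sl]))
    total = float(np.trace(A))
    return total, per_term, XtWX, P


def fit_ordinal_gam(
    spec: OrdinalGamSpec,
    data: pd.DataFrame,
    response: str = "label",
    weights: np.ndarray | None = None,
    lambdas: np.ndarray | str = "select",
    lambda_grid: np.ndarray | None = None,
    refine: bool = True,
    max_iter: int = 200,
) -> OrdinalGamFit:
    """Fit the cumulative-logit additive model.

    ``weights`` are prior/frequency weights (default 1).  ``lambdas``
    may be an explicit vector of smoothing parameters (one per penalty)
    or ``"select"`` for coordinate-wise AIC grid search over
    ``lambda_grid`` (default 15 points, log10 from -3 to 4, with one
    local refinement pass).
    """
    y = _encode_response(data[response])
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("need at least 2 response categories present")
    X, blocks, n_lam = _build_blocks(spec, data)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)

    # only the unpenalised part needs full column rank; ridge/spline
    # penalties regularise their own blocks (e.g. random intercepts
    # overlapping the global intercept)
    unpen = np.ones(X.shape[1], dtype=bool)
    for blk in blocks:
        if blk.penalties:
            unpen[blk.sl] = False
    Xu = X[:, unpen]
    if Xu.shape[1] <= 200 and np.linalg.matrix_rank(Xu) < Xu.shape[1]:
        warnings.warn("unpenalised design columns are rank deficient")

    if isinstance(lambdas, str):
        if n_lam == 0:
            lam = np.zeros(0)
        else:
            grid = (np.logspace(-3, 4, 15) if lambda_grid is None
                    else np.asarray(lambda_grid, dtype=float))
            lam = np.full(n_lam, 1.0)
            beta_ws, th_ws = None, 1.0
            best_aic = np.inf

            def aic_at(lam_vec, b0, t0):
                b, t2, _, ll, conv, _ = _fit_inner(X, y, blocks, lam_vec, w, b0, t0,
                                                   max_iter=max_iter)
                edf_tot, _, _, _ = _edf(X, y, b, t2, blocks, lam_vec, w)
                return -2.0 * ll + 2.0 * (edf_tot + 1.0), b, t2

            n_pass = 2 if refine else 1
            for sweep in range(n_pass):
                for j in range(n_lam):
                    best_j = lam[j]
                    for g in grid:
                        trial = lam.copy()
                        trial[j] = g
                        a, b, t2 = aic_at(trial, beta_ws, th_ws)
                        if a < best_aic - 1e-9:
                            best_aic, best_j = a, g
                            beta_ws, th_ws = b, t2
                    lam[j] = best_j
                if sweep == 0 and refine:
                    grid = np.unique(np.concatenate(
                        [grid, *[lam * f for f in (0.3, 3.0)]]))
    else:
        lam = np.asarray(lambdas, dtype=float)
        if lam.size != n_lam:
            raise ValueError(f"expected {n_lam} smoothing parameters, got {lam.size}")

    beta, theta2, pen_ll, ll, converged, it = _fit_inner(
        X, y, blocks, lam, w, max_iter=max_iter)
    if not converged:
        warnings.warn("ordinal model did not converge; returning best iterate")
    edf_tot, edf_term, XtWX, P = _edf(X, y, beta, theta2, blocks, lam, w)
    aic = -2.0 * ll + 2.0 * (edf_tot + 1.0)

    # covariance of (beta, theta2) from the penalized observed information
    p = X.shape[1]
    _, _, d_th, h_ee, h_et, h_tt = _cumlogit_derivs(y, X @ beta, theta2)
    H = np.empty((p + 1, p + 1))
    H[:p, :p] = XtWX + P
    cross = -X.T @ (w * h_et)
    H[:p, p] = cross
    H[p, :p] = cross
    H[p, p] = -float(w @ h_tt)
    try:
        cov = np.linalg.inv(H + 1e-10 * np.eye(p + 1))
    except np.linalg.LinAlgError:
        cov = None

    reference = {}
    for term in spec.terms:
        for c in term.columns:
            if c in data.columns and data[c].dtype.kind in "iuf":
                reference[c] = float(np.median(data[c]))
            elif c in data.columns:
                reference[c] = data[c].astype(str).mode().iloc[0]
        if term.by is not None:
            reference[term.by] = data[term.by].astype(str).mode().iloc[0]

    return OrdinalGamFit(
        spec=spec, beta=beta, theta2=float(theta2), lambdas=lam, blocks=blocks,
        loglik=ll, penalized_loglik=pen_ll, edf_total=edf_tot,
        edf_by_term=edf_term, aic=aic, converged=converged, iterations=it,
        cov=cov, reference=reference,
    )


def design_for(fit: OrdinalGamFit, data: pd.DataFrame) -> np.ndarray:
    """Design matrix for new data under the fitted model's bases."""
    cols = [np.ones((len(data), 1))]
    for blk in fit.blocks:
        cols.append(blk.predictor(data))
    return np.hstack(cols)


def predict_eta(
    fit: OrdinalGamFit,
    data: pd.DataFrame,
    exclude: tuple[str, ...] = (),
    with_se: bool = False,
):
    """Linear predictor at new data; optionally exclude terms by name.

    Random-intercept blocks can be excluded (set to their population
    mean 0) by listing their term name.
    """
    X = design_for(fit, data)
    mask = np.ones(X.shape[1], dtype=bool)
    for blk in fit.blocks:
        if blk.term.name in exclude:
            mask[blk.sl] = False
    eta = X[:, mask] @ fit.beta[mask]
    if not with_se:
        return eta
    cov_b = fit.cov[: X.shape[1], : X.shape[1]]
    Xm = np.where(mask[None, :], X, 0.0)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xm, cov_b, Xm), 0.0))
    return eta, se


def predict_probabilities(
    fit: OrdinalGamFit,
    data: pd.DataFrame,
    exclude: tuple[str, ...] = (),
    with_se: bool = False,
):
    """Per-category probabilities (and delta-method SEs) at new data."""
    if with_se:
        eta, se_eta = predict_eta(fit, data, exclude, with_se=True)
    else:
        eta = predict_eta(fit, data, exclude)
    probs = category_probs(eta, fit.theta2)
    if not with_se:
        return probs
    F1 = expit(THETA1 - eta)
    F2 = expit(fit.theta2 - eta)
    f1, f2 = F1 * (1 - F1), F2 * (1 - F2)
    dp = np.column_stack([-f1, f1 - f2, f2])  # dP_k / d eta
    return probs, np.abs(dp) * se_eta[:, None]


def reference_frame(fit: OrdinalGamFit, n: int, overrides: dict) -> pd.DataFrame:
    """Data frame of reference covariate values with selected overrides."""
    base = {}
    for key, val in (fit.reference or {}).items():
        base[key] = [val] * n
    frame = pd.DataFrame(base)
    for key, val in overrides.items():
        frame[key] = val
    return frame


def predict_surface(
    fit: OrdinalGamFit,
    dir_grid: np.ndarray | None = None,
    wind_grid: np.ndarray | None = None,
    exclude_random: bool = True,
) -> dict:
    """Probability (and SE) surfaces over wind direction x strength.

    Other covariates sit at their reference values (medians / modes) and
    random intercepts at zero.
    """
    if dir_grid is None:
        dir_grid = np.arange(0.0, 360.1, 5.0)
    if wind_grid is None:
        wind_grid = np.linspace(0.0, 60.0, 31)
    D, W = np.meshgrid(dir_grid, wind_grid)
    excl = tuple(b.term.name for b in fit.blocks if b.term.kind == "random") \
        if exclude_random else ()
    frame = reference_frame(fit, D.size, {"wind_dir_deg": D.ravel(),
                                          "wind_kmh": W.ravel()})
    probs, se = predict_probabilities(fit, frame, exclude=excl, with_se=True)
    return {
        "dir_deg": dir_grid,
        "wind_kmh": wind_grid,
        "prob": {c: probs[:, i].reshape(D.shape) for i, c in enumerate(CATEGORIES)},
        "se": {c: se[:, i].reshape(D.shape) for i, c in enumerate(CATEGORIES)},
    }


def confusion_matrix(fit: OrdinalGamFit, data: pd.DataFrame,
                     response: str = "label") -> pd.DataFrame:
    """3x3 observed (rows) vs modal-predicted (columns) fix counts."""
    y = _encode_response(data[response])
    probs = predict_probabilities(fit, data)
    pred = probs.argmax(axis=1) + 1
    mat = np.zeros((3, 3), dtype=int)
    for obs, pr in zip(y, pred):
        mat[obs - 1, pr - 1] += 1
    return pd.DataFrame(mat, index=[f"{c} (observed)" for c in CATEGORIES],
                        columns=[f"{c} (predicted)" for c in CATEGORIES])


def select_model(
    candidates: list[tuple[str, OrdinalGamSpec]],
    data: pd.DataFrame,
    response: str = "label",
    weights: np.ndarray | None = None,
    lambdas: np.ndarray | str = "select",
    nested: list[tuple[str, str]] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit candidate specifications and tabulate AIC / EDF / LRTs.

    ``nested`` lists (smaller, larger) name pairs for likelihood-ratio
    tests; the chi-squared df is the EDF difference.  Requesting a test
    for a non-nested pair (by term names) raises.
    """
    from scipy.stats import chi2

    fits: dict[str, OrdinalGamFit] = {}
    rows = []
    for name, spec in candidates:
        fit = fit_ordinal_gam(spec, data, response, weights, lambdas, **fit_kwargs)
        fits[name] = fit
        rows.append({"model": name, "loglik": fit.loglik, "edf": fit.edf_total,
                     "aic": fit.aic})
    table = pd.DataFrame(rows)
    table["lrt_chi2"] = np.nan
    table["lrt_df"] = np.nan
    table["lrt_p"] = np.nan
    for small, large in nested or []:
        t_small = {t.name for t in fits[small].spec.terms}
        t_large = {t.name for t in fits[large].spec.terms}
        if not t_small <= t_large:
            raise ValueError(f"{small!r} is not nested in {large!r}")
        stat = 2.0 * (fits[large].loglik - fits[small].loglik)
        df = max(fits[large].edf_total - fits[small].edf_total, 1e-6)
        idx = table.index[table["model"] == large][0]
        table.loc[idx, ["lrt_chi2", "lrt_df", "lrt_p"]] = (
            stat, df, float(chi2.sf(max(stat, 0.0), df)))
    table.attrs["fits"] = fits
    return table
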