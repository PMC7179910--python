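"""AR1 linear mixed-effects inference and marginal-means contrasts.

The response (standardized log velocity) is modelled as

    y = X beta + Z_id b_id + Z_type b_type + e

with independent (crossed) random intercepts for individual and for record
provenance ("Type": True vs Predicted velocity), and residuals following a
first-order autoregressive correlation by observation order within
individual.  Fitting is by maximum likelihood: the two variance ratios and
the AR1 coefficient are optimized numerically with beta and the residual
variance profiled out in closed form.  The AR1 correlation inverse is
tridiagonal, so a Woodbury identity gives the exact marginal likelihood in
O(n) per evaluation — tests verify it against the dense multivariate-normal
log-density.

Estimated marginal means average the model-implied cell means equally over
the levels of factors not in the requested grid, with numeric covariates
held at their sample means; all-pairwise contrasts within a family are
adjusted by the studentized-range (Tukey) method.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrices
from scipy import optimize
from scipy.stats import studentized_range, t as t_dist

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EmmResult",
    "ConvergenceError",
    "build_candidate_models",
    "fit_lme",
    "rank_aic",
    "fit_final_model",
    "estimate_marginal_means",
    "pairwise_contrasts",
    "FINAL_FORMULA",
]

FINAL_FORMULA = "C(LunarDiel) * C(Season) * C(Species)"


class ConvergenceError(RuntimeError):
    """Raised when every optimizer restart fails; carries the traces."""

    def __init__(self, message: str, traces: list):
        super().__init__(message)
        self.traces = traces


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effects structure.

    All candidates share the random-intercept factors (individual ID and
    Type) and the AR1 residual correlation; only the fixed part varies.
    """

    label: str
    formula: str  # patsy right-hand side

    @property
    def fixed_terms(self) -> list[str]:
        from patsy import ModelDesc
        desc = ModelDesc.from_formula("y ~ " + self.formula)
        return [t.name() for t in desc.rhs_termlist]


def build_candidate_models() -> list[ModelSpec]:
    """The nine competing fixed-effect structures over SunAlt,
    MoonIlluminatedFrac and TMAX: three single, three additive, three
    interactive."""
    formulas = [
        ("1", "SunAlt"),
        ("2", "MoonIlluminatedFrac"),
        ("3", "TMAX"),
        ("4", "SunAlt + MoonIlluminatedFrac"),
        ("5", "SunAlt + TMAX"),
        ("6", "SunAlt + MoonIlluminatedFrac + TMAX"),
        ("7", "SunAlt * MoonIlluminatedFrac"),
        ("8", "SunAlt * TMAX"),
        ("9", "SunAlt * MoonIlluminatedFrac * TMAX"),
    ]
    return [ModelSpec(label, f) for label, f in formulas]


# ---------------------------------------------------------------------------
# AR1 machinery


def _ar1_apply_inverse(M: np.ndarray, phi: float,
                       first: np.ndarray, last: np.ndarray) -> np.ndarray:
    """Apply the inverse AR1 block-correlation matrix to columns of M.

    ``first``/``last`` flag the first/last row of each individual's block.
    The inverse is tridiagonal: scaled by 1/(1-phi^2), diagonal 1 at block
    edges and 1+phi^2 inside, off-diagonal -phi; singleton blocks reduce to
    the identity.
    """
    n = M.shape[0]
    prev_same = ~first
    next_same = ~last
    a = np.ones(n)
    a[prev_same & next_same] = 1.0 + phi * phi
    a[first & last] = 1.0 - phi * phi  # singleton block: C = I
    out = a[:, None] * M
    out[1:] -= phi * np.where(prev_same[1:, None], M[:-1], 0.0)
    out[:-1] -= phi * np.where(next_same[:-1, None], M[1:], 0.0)
    return out / (1.0 - phi * phi)


def _block_flags(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(groups)
    first = np.ones(n, dtype=bool)
    first[1:] = groups[1:] != groups[:-1]
    last = np.ones(n, dtype=bool)
    last[:-1] = first[1:]
    return first, last


def _profiled_negll(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                    Z: np.ndarray, first: np.ndarray, last: np.ndarray,
                    n_re: tuple[int, ...]) -> float:
    """Negative profiled ML log-likelihood at variance parameters theta.

    theta = (log lambda_1, ..., log lambda_K, arctanh phi) where lambda_k is
    the ratio of the k-th random-intercept variance to the residual variance.
    """
    nll, *_ = _profiled_pieces(theta, y, X, Z, first, last, n_re)
    return nll


def _profiled_pieces(theta, y, X, Z, first, last, n_re):
    n, p = X.shape
    q = Z.shape[1]
    lam = np.exp(theta[:-1])
    phi = np.tanh(theta[-1])
    # per-column sqrt(lambda): each random factor contributes its own ratio
    sqrt_lam = np.concatenate([
        np.full(k, np.sqrt(lam[j])) for j, k in enumerate(n_re)]) if q else np.empty(0)

    A = np.column_stack([X, y])
    CiA = _ar1_apply_inverse(A, phi, first, last)
    AtCiA = A.T @ CiA
    if q:
        CiZ = _ar1_apply_inverse(Z, phi, first, last)
        S_zz = Z.T @ CiZ
        S_za = Z.T @ CiA
        Ls = sqrt_lam[:, None]
        Mmat = np.eye(q) + Ls * S_zz * sqrt_lam[None, :]
        try:
            cf = np.linalg.cholesky(Mmat)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None, None
        half = np.linalg.solve(cf, Ls * S_za)  # q x (p+1)
        AtViA = AtCiA - half.T @ half
        logdet_M = 2.0 * np.log(np.diag(cf)).sum()
    else:
        AtViA = AtCiA
        logdet_M = 0.0
    n_blocks = int(first.sum())
    logdet_C = (n - n_blocks) * np.log1p(-phi * phi)
    logdet_V0 = logdet_C + logdet_M

    XtViX = AtViA[:p, :p]
    XtViy = AtViA[:p, p]
    ytViy = AtViA[p, p]
    # minimum-norm GLS: rank-deficient designs (empty factor cells) must not
    # leak huge null-space components into beta — estimable combinations stay
    # exact, non-estimable ones are flagged downstream
    beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
    rss = float(ytViy - beta @ XtViy)
    if rss <= 0 or not np.isfinite(rss):
        return np.inf, None, None, None, None
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet_V0)
    return -ll, beta, sigma2, XtViX, (lam, phi)


@dataclass
class ModelFit:
    """A fitted AR1 mixed model (maximum likelihood)."""

    label: str
    formula: str
    params: pd.Series           # fixed-effect estimates
    bse: pd.Series              # standard errors
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame    # covariance of the fixed effects
    sigma2: float               # residual variance
    phi: float                  # AR1 coefficient
    re_variances: dict[str, float]  # variance component per random factor
    loglik: float
    df_model: int               # parameters counted for AIC
    nobs: int
    rank: int                   # rank of the fixed design
    design_info: object = field(repr=False)
    rowspace: np.ndarray = field(repr=False, default=None)
    covariate_means: dict[str, float] = field(default_factory=dict)
    factor_levels: dict[str, list] = field(default_factory=dict)
    boundary: list[str] = field(default_factory=list)
    optimizer_trace: object = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.df_model

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.nobs) * self.df_model

    @property
    def ddf(self) -> int:
        """Residual degrees of freedom used for t statistics and CIs."""
        return self.nobs - self.rank


_STARTS = [
    np.array([-1.0, -1.0, np.arctanh(0.5)]),
    np.array([-3.0, -3.0, 0.0]),
    np.array([0.5, 0.5, np.arctanh(0.9)]),
]

_BOUNDS = [(-15.0, 8.0), (-15.0, 8.0), (-6.0, 6.0)]


def fit_lme(spec: ModelSpec | str, data: pd.DataFrame,
            response: str = "log_velocity",
            group_col: str = "individual_id",
            random_factors: tuple[str, ...] = ("individual_id", "type"),
            order_col: str = "timestamp") -> ModelFit:
    """Fit one AR1 random-intercepts model by maximum likelihood.

    Rows are ordered by (individual, time) internally, so the fit is
    invariant to row permutation of ``data``.  The AR1 correlation runs over
    observation order within individual.  Raises ``ConvergenceError`` if all
    optimizer restarts fail; a variance component estimated at its lower
    boundary is reported in ``fit.boundary``.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec, spec)
    df = data.sort_values([group_col, order_col], kind="mergesort").reset_index(drop=True)

    y_dm, X_dm = dmatrices(f"{response} ~ {spec.formula}", df,
                           return_type="dataframe")
    y = y_dm.to_numpy()[:, 0]
    X = X_dm.to_numpy()
    names = list(X_dm.columns)
    design_info = X_dm.design_info

    Z_parts, n_re = [], []
    for fac in random_factors:
        dummies = pd.get_dummies(df[fac].astype(str))
        Z_parts.append(dummies.to_numpy(dtype=float))
        n_re.append(dummies.shape[1])
    Z = np.hstack(Z_parts) if Z_parts else np.empty((len(df), 0))

    groups = df[group_col].to_numpy()
    first, last = _block_flags(groups)

    best, traces = None, []
    for x0 in _STARTS:
        x0k = x0 if len(n_re) == 2 else np.concatenate(
            [x0[:1] * np.ones(len(n_re)), x0[-1:]])
        res = optimize.minimize(
            _profiled_negll, x0k,
            args=(y, X, Z, first, last, tuple(n_re)),
            method="L-BFGS-B", bounds=_BOUNDS[:len(n_re)] + [_BOUNDS[-1]],
            options={"maxiter": 500, "ftol": 1e-10})
        traces.append(res)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
    if best is None:
        raise ConvergenceError("AR1 mixed-model fit failed from all starting "
                               "values", traces)

    nll, beta, sigma2, XtViX, (lam, phi) = _profiled_pieces(
        best.x, y, X, Z, first, last, tuple(n_re))
    n, p = X.shape
    _, sv, Vt = np.linalg.svd(X, full_matrices=False)
    keep = sv > sv[0] * 1e-10
    rank = int(keep.sum())
    rowspace = Vt[keep].T  # orthonormal basis of estimable directions
    cov_beta = sigma2 * np.linalg.pinv(XtViX)
    bse = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / bse, np.nan)
    ddf = n - rank
    pvals = 2.0 * t_dist.sf(np.abs(tvals), ddf)

    re_vars = {fac: float(lam[j] * sigma2)
               for j, fac in enumerate(random_factors)}
    boundary = [fac for j, fac in enumerate(random_factors)
                if best.x[j] <= _BOUNDS[j][0] + 1e-6]

    covariate_means, factor_levels = {}, {}
    for fi in design_info.factor_infos.values():
        var = fi.factor.name()
        col = var[2:-1] if var.startswith("C(") else var
        if fi.type == "categorical":
            factor_levels[col] = list(fi.categories)
        else:
            covariate_means[col] = float(df[col].mean())

    return ModelFit(
        label=spec.label, formula=spec.formula,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2=float(sigma2), phi=float(phi), re_variances=re_vars,
        loglik=float(-nll), df_model=p + len(n_re) + 2,  # + phi + sigma2
        nobs=n, rank=rank, design_info=design_info, rowspace=rowspace,
        covariate_means=covariate_means, factor_levels=factor_levels,
        boundary=boundary, optimizer_trace=best)


def rank_aic(fits: list[ModelFit]) -> pd.DataFrame:
    """AIC ranking table (ascending), with delta-AIC, BIC and logLik."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to rank")
    ns = {f.nobs for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits use differing row counts {sorted(ns)}; "
                         "AIC values are not comparable")
    rows = [{"model": f.label, "formula": f.formula, "df": f.df_model,
             "AIC": f.aic, "BIC": f.bic, "logLik": f.loglik} for f in fits]
    out = pd.DataFrame(rows).sort_values("AIC", kind="mergesort")
    out["dAIC"] = out["AIC"] - out["AIC"].min()
    return out.reset_index(drop=True)


def fit_final_model(data: pd.DataFrame, **kwargs) -> ModelFit:
    """The interactive LunarDiel x Season x Species model.

    Empty factor cells are reported (the fit proceeds; non-estimable
    contrasts surface as rank deficiency).
    """
    counts = data.groupby(["LunarDiel", "Season", "Species"], observed=True).size()
    full = (data["LunarDiel"].nunique() * data["Season"].nunique()
            * data["Species"].nunique())
    if len(counts) < full:
        import logging
        logging.getLogger(__name__).warning(
            "final model: %d of %d factor cells are empty",
            full - len(counts), full)
    return fit_lme(ModelSpec("final", FINAL_FORMULA), data, **kwargs)


# ---------------------------------------------------------------------------
# Estimated marginal means and Tukey contrasts


@dataclass
class EmmResult:
    """Marginal means over a factor grid, with the pieces contrasts need."""

    grid: pd.DataFrame          # factor columns + emmean, SE, df, lower, upper
    L: np.ndarray               # grid rows in fixed-effect coefficient space
    cov_beta: np.ndarray
    ddf: int
    factors: list[str]
    rowspace: np.ndarray | None = None  # estimable-direction basis


def _estimable(L: np.ndarray, rowspace: np.ndarray | None) -> np.ndarray:
    """Which rows of L lie in the design's row space (are estimable)."""
    if rowspace is None:
        return np.ones(len(L), dtype=bool)
    resid = L - (L @ rowspace) @ rowspace.T
    scale = np.maximum(np.abs(L).max(axis=1), 1.0)
    return np.abs(resid).max(axis=1) < 1e-8 * scale


def estimate_marginal_means(fit: ModelFit, factors: list[str],
                            alpha: float = 0.05) -> EmmResult:
    """Model-implied means on the reference grid of the requested factors.

    Factors absent from ``factors`` are averaged over with equal weight per
    level; numeric covariates sit at their sample means.  Cells whose
    contrast is not estimable within the design's column space are flagged.
    """
    all_factors = dict(fit.factor_levels)
    for f in factors:
        if f not in all_factors:
            raise ValueError(f"{f!r} is not a categorical factor of the model")
    names = list(all_factors)
    combos = list(itertools.product(*[all_factors[f] for f in names]))
    ref = pd.DataFrame(combos, columns=names)
    for cov, mean in fit.covariate_means.items():
        ref[cov] = mean
    (L_full,) = build_design_matrices([fit.design_info], ref)
    L_full = np.asarray(L_full)

    keys = ref[factors]
    grid_rows, L_rows = [], []
    for levels, idx in keys.groupby(factors, sort=False).groups.items():
        if not isinstance(levels, tuple):
            levels = (levels,)
        L_avg = L_full[np.asarray(idx)].mean(axis=0)
        grid_rows.append(dict(zip(factors, levels)))
        L_rows.append(L_avg)
    L = np.vstack(L_rows)

    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    emm = L @ beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", L, cov, L), 0.0, None))
    ok = _estimable(L, fit.rowspace)
    emm = np.where(ok, emm, np.nan)  # flagged, not silently dropped
    se = np.where(ok, se, np.nan)
    ddf = fit.ddf
    tcrit = t_dist.ppf(1 - alpha / 2, ddf)
    grid = pd.DataFrame(grid_rows)
    grid["emmean"] = emm
    grid["SE"] = se
    grid["df"] = ddf
    grid["lower"] = emm - tcrit * se
    grid["upper"] = emm + tcrit * se
    grid["estimable"] = ok
    return EmmResult(grid=grid, L=L, cov_beta=cov, ddf=ddf, factors=factors,
                     rowspace=fit.rowspace)


def _cell_label(row: pd.Series, cols: list[str]) -> str:
    return " ".join(str(row[c]) for c in cols)


def pairwise_contrasts(emm: EmmResult, group_by: list[str] | None = None,
                       adjust: str = "tukey") -> pd.DataFrame:
    """All pairwise differences of marginal means within each family.

    A family is the set of grid cells sharing the ``group_by`` values (all
    cells when ``group_by`` is None).  Tukey adjustment uses the studentized
    range with the family's cell count; families of size 1 yield no rows.
    """
    if adjust not in ("tukey", "none"):
        raise ValueError("adjust must be 'tukey' or 'none'")
    group_by = group_by or []
    grid = emm.grid
    contrast_cols = [f for f in emm.factors if f not in group_by]
    beta_cov = emm.cov_beta
    # scipy's studentized range integrator struggles at very large df; the
    # distribution is asymptotically df-free, so cap (difference < 1e-4)
    ddf = min(emm.ddf, 2000)
    families = (grid.groupby(group_by, sort=False) if group_by
                else [((), grid)])
    out = []
    for gkey, fam in families:
        if not isinstance(gkey, tuple):
            gkey = (gkey,)
        k = len(fam)
        if k < 2:
            continue
        pos = [grid.index.get_loc(i) for i in fam.index]
        for i, j in itertools.combinations(pos, 2):
            d = emm.L[i] - emm.L[j]
            if not _estimable(d[None, :], emm.rowspace)[0]:
                est = se = tratio = p = np.nan  # non-estimable contrast
                rec = dict(zip(group_by, gkey))
                rec.update({
                    "contrast":
                        f"{_cell_label(grid.iloc[i], contrast_cols)} - "
                        f"{_cell_label(grid.iloc[j], contrast_cols)}",
                    "estimate": est, "SE": se, "df": emm.ddf,
                    "t.ratio": tratio, "p.value": p,
                })
                out.append(rec)
                continue
            est = float(grid["emmean"].iloc[i] - grid["emmean"].iloc[j])
            se = float(np.sqrt(max(d @ beta_cov @ d, 0.0)))
            tratio = est / se if se > 0 else 0.0
            if tratio == 0.0:
                p = 1.0
            elif adjust == "tukey":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # quad chatter at large q
                    p = float(studentized_range.sf(np.sqrt(2.0) * abs(tratio),
                                                   k, ddf))
            else:
                p = float(2.0 * t_dist.sf(abs(tratio), ddf))
            rec = dict(zip(group_by, gkey))
            rec.update({
                "contrast": f"{_cell_label(grid.iloc[i], contrast_cols)} - "
                            f"{_cell_label(grid.iloc[j], contrast_cols)}",
                "estimate": est, "SE": se, "df": emm.ddf, "t.ratio": tratio,
                "p.value": float(np.clip(p, 0.0, 1.0)),
            })
            out.append(rec)
    cols = group_by + ["contrast", "estimate", "SE", "df", "t.ratio", "p.value"]
    return pd.DataFrame(out, columns=cols)
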