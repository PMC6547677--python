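"""Maximum-likelihood linear mixed models with structured residuals.

The model family fitted here is

    y_d = X_d beta + Z_d b_d + S_d v_d + e_d            (cluster d)

with ``b_d ~ N(0, G0)`` (an unstructured covariance over a small set of
cluster-level random-effect columns), optional iid subject intercepts
``v_d ~ N(0, tau^2 I)`` nested in the cluster, and residuals ``e_d ~
N(0, D C(phi) D)`` where ``C`` is block-AR(1) within each time series
inside the cluster and ``D`` holds (possibly group-specific) residual
standard deviations. Estimation is profiled maximum likelihood: for a
candidate covariance parameter vector the GLS fixed effects and the
deviance are computed in closed form per cluster, and the covariance
parameters are optimised numerically. Clusters sharing an identical
layout are processed as one batched linear-algebra call, which keeps
replicate simulation studies cheap.

Covariance parameters use an unconstrained scale (log standard
deviations, atanh correlations), so likelihood-ratio tests across
nested random structures and profile-likelihood intervals are
straightforward. Denominator degrees of freedom follow the
between-within rule: each fixed effect receives the degrees of freedom
of the innermost grouping level at which its column varies, with the
intercept assigned to the innermost level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_PD_PENALTY = 1e10
_LOG_SD_BOUNDS = (-8.0, 5.0)
_ATANH_BOUNDS = (-6.0, 6.0)


class ConvergenceError(RuntimeError):
    """Optimiser failed; carries the scipy result for diagnostics."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


@dataclass
class LMMSpec:
    """Declarative description of one mixed model.

    ``re`` names design columns receiving correlated cluster-level
    random effects; ``subject`` names a column whose levels (nested in
    the cluster) receive iid random intercepts; ``series``/``time``
    define the AR(1) residual blocks; ``var_group`` switches on
    heterogeneous residual variances by group.
    """

    y: str
    x: list[str]
    cluster: str
    re: list[str] = field(default_factory=list)
    subject: str | None = None
    ar1: bool = False
    series: str | None = None
    time: str | None = None
    var_group: str | None = None
    re_structure: str = "unstructured"  # or "diagonal"
    method: str = "ml"  # or "reml"

    def covariance_param_names(self, var_levels: list) -> list[str]:
        names = [f"log_sd({c})" for c in self.re]
        if self.re_structure == "unstructured":
            names += [
                f"atanh_r({a},{b})" for a, b in itertools.combinations(self.re, 2)
            ]
        if self.subject:
            names.append(f"log_sd({self.subject})")
        if self.ar1:
            names.append("atanh_phi")
        names += [f"log_sigma({lv})" for lv in var_levels]
        return names


@dataclass
class LMMFit:
    spec: LMMSpec
    theta: dict[str, float]
    beta: pd.Series
    cov_beta: np.ndarray
    fixed: pd.DataFrame
    loglik: float
    deviance: float
    n_obs: int
    n_cov_params: int
    G0: pd.DataFrame
    tau2: float | None
    phi: float | None
    sigma2: dict
    blups: pd.DataFrame
    df_by_term: pd.Series
    converged: bool
    boundary: bool
    message: str
    problem: "_LMMProblem"

    @property
    def re_variances(self) -> dict[str, float]:
        return {c: float(self.G0.loc[c, c]) for c in self.spec.re}

    def contrast(self, weights: dict[str, float], df: float | None = None) -> dict:
        """Estimate, SE and t-test for a linear combination of fixed effects."""
        c = np.array([weights.get(t, 0.0) for t in self.beta.index])
        est = float(c @ self.beta.to_numpy())
        se = float(np.sqrt(c @ self.cov_beta @ c))
        if df is None:
            df = float(min(self.df_by_term[t] for t, w in weights.items() if w != 0.0))
        t_val = est / se if se > 0 else 0.0
        tcrit = stats.t.ppf(0.975, df)
        return {
            "estimate": est,
            "se": se,
            "ci_lower": est - tcrit * se,
            "ci_upper": est + tcrit * se,
            "t_value": t_val,
            "df": df,
            "p_value": 2 * stats.t.sf(abs(t_val), df),
        }


def effect_size_r(t: float, df: float) -> float:
    """Partial effect size r = t / sqrt(t^2 + df), signed like t."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(t / math.sqrt(t * t + df))


def between_within_df(df: pd.DataFrame, x_cols: list[str], cluster: str,
                      subject: str | None = None) -> pd.Series:
    """Between-within denominator df for each fixed-effect column.

    Levels are [cluster, (subject,) observation]; a column is assigned
    to the innermost level at which it varies, the intercept (any
    constant column) to the innermost level. df at a level equals the
    number of units at that level minus units one level up minus the
    count of fixed effects assigned to the level.
    """
    levels = [cluster] + ([subject] if subject else [])
    m = [1] + [df[lv].nunique() for lv in levels] + [len(df)]
    assign = {}
    for col in x_cols:
        vals = df[col]
        if vals.nunique() <= 1:
            assign[col] = len(levels)  # constant: innermost
            continue
        lvl = 0
        for i, lv in enumerate(levels):
            if df.groupby(lv, sort=False)[col].nunique().max() > 1:
                lvl = i + 1
            else:
                break
        assign[col] = lvl
    counts = {lv: sum(1 for c in assign.values() if c == lv) for lv in set(assign.values())}
    out = {}
    for col, lvl in assign.items():
        out[col] = m[lvl + 1] - m[lvl] - counts[lvl]
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# internal problem representation
# ---------------------------------------------------------------------------

class _ClusterGroup:
    """A batch of clusters sharing one layout (stacked 3-D arrays)."""

    def __init__(self, ids, X, y, Z, S, corr_template, var_idx):
        self.ids = ids            # list of cluster labels
        self.X = X                # (C, n, p)
        self.y = y                # (C, n)
        self.Z = Z                # (C, n, q) or None
        self.S = S                # (n, m) subject one-hot or None (same layout)
        self.corr_template = corr_template  # (n, n) |dt| matrix masked by series, or None
        self.var_idx = var_idx    # (n,) residual variance-group index


class _LMMProblem:
    def __init__(self, df: pd.DataFrame, spec: LMMSpec):
        self.spec = spec
        sort_cols = [spec.cluster]
        if spec.subject:
            sort_cols.append(spec.subject)
        if spec.series:
            sort_cols.append(spec.series)
        if spec.time:
            sort_cols.append(spec.time)
        data = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        self.data = data
        self.var_levels = (
            sorted(data[spec.var_group].unique()) if spec.var_group else ["resid"]
        )
        self.param_names = spec.covariance_param_names(self.var_levels)
        self.q = len(spec.re)
        self.n_obs = len(data)
        self.p = len(spec.x)

        groups: dict[tuple, list] = {}
        for cid, g in data.groupby(spec.cluster, sort=True):
            X = g[spec.x].to_numpy(dtype=float)
            y = g[spec.y].to_numpy(dtype=float)
            Z = g[spec.re].to_numpy(dtype=float) if self.q else None
            if spec.subject:
                codes = pd.factorize(g[spec.subject])[0]
                m = codes.max() + 1
                S = np.zeros((len(g), m))
                S[np.arange(len(g)), codes] = 1.0
                s_key = tuple(codes)
            else:
                S, s_key = None, ()
            if spec.ar1:
                t = g[spec.time].to_numpy(dtype=float)
                sid = pd.factorize(g[spec.series])[0]
                dt = np.abs(t[:, None] - t[None, :])
                same = sid[:, None] == sid[None, :]
                corr = np.where(same, dt, np.inf)
                c_key = tuple(np.round(corr[np.isfinite(corr)], 9)) + tuple(sid)
            else:
                corr, c_key = None, ()
            if spec.var_group:
                v_idx = np.array([self.var_levels.index(v) for v in g[spec.var_group]])
            else:
                v_idx = np.zeros(len(g), dtype=int)
            key = (len(g), s_key, c_key, tuple(v_idx))
            groups.setdefault(key, []).append((cid, X, y, Z, S, corr, v_idx))

        self.groups: list[_ClusterGroup] = []
        for key, items in groups.items():
            ids = [it[0] for it in items]
            X = np.stack([it[1] for it in items])
            y = np.stack([it[2] for it in items])
            Z = np.stack([it[3] for it in items]) if self.q else None
            S = items[0][4]
            corr = items[0][5]
            var_idx = items[0][6]
            self.groups.append(_ClusterGroup(ids, X, y, Z, S, corr, var_idx))

    # -- parameter unpacking ------------------------------------------------
    def unpack(self, theta: np.ndarray) -> dict:
        spec, q = self.spec, self.q
        i = 0
        sds = np.exp(theta[i:i + q]); i += q
        if q and spec.re_structure == "unstructured":
            n_r = q * (q - 1) // 2
            rs = np.tanh(theta[i:i + n_r]); i += n_r
        else:
            rs = np.zeros(q * (q - 1) // 2)
        Rm = np.eye(q)
        if q:
            k = 0
            for a, b in itertools.combinations(range(q), 2):
                Rm[a, b] = Rm[b, a] = rs[k]
                k += 1
        G0 = np.outer(sds, sds) * Rm if q else np.zeros((0, 0))
        tau2 = None
        if spec.subject:
            tau2 = float(np.exp(theta[i]) ** 2); i += 1
        phi = None
        if spec.ar1:
            phi = float(np.tanh(theta[i])); i += 1
        sigmas = np.exp(theta[i:i + len(self.var_levels)])
        return {"G0": G0, "tau2": tau2, "phi": phi, "sigmas": sigmas}

    def _resid_cov(self, grp: _ClusterGroup, phi, sigmas) -> np.ndarray:
        d = sigmas[grp.var_idx]
        n = len(grp.var_idx)
        if grp.corr_template is None or phi is None:
            C = np.eye(n)
        else:
            # phi^|dt| within a series, 0 across series; phi may be negative
            finite = np.isfinite(grp.corr_template)
            C = np.zeros((n, n))
            dt = grp.corr_template[finite]
            C[finite] = np.sign(phi) ** np.round(dt) * np.abs(phi) ** dt
        return d[:, None] * C * d[None, :]

    # -- deviance -----------------------------------------------------------
    def deviance_beta(self, theta: np.ndarray):
        pars = self.unpack(theta)
        G0, tau2, phi, sigmas = pars["G0"], pars["tau2"], pars["phi"], pars["sigmas"]
        penalty = 0.0
        if self.q:
            # pairwise tanh correlations can leave the PD cone for q >= 3;
            # project onto it smoothly so the optimiser keeps gradient signal
            w, Q = np.linalg.eigh(G0)
            if w.min() < 1e-10:
                penalty = 1e5 * float(np.sum(np.minimum(w, 0.0) ** 2)) + 1.0
                G0 = Q @ np.diag(np.clip(w, 1e-10, None)) @ Q.T
                pars["G0"] = G0
        XtWX = np.zeros((self.p, self.p))
        XtWy = np.zeros(self.p)
        logdet = 0.0
        cache = []
        for grp in self.groups:
            n = grp.X.shape[1]
            R = self._resid_cov(grp, phi, sigmas)
            V = np.broadcast_to(R, (len(grp.ids), n, n)).copy()
            if self.q:
                V += grp.Z @ G0 @ np.swapaxes(grp.Z, 1, 2)
            if tau2 is not None and grp.S is not None:
                V += tau2 * (grp.S @ grp.S.T)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return _PD_PENALTY, None, None
            logdet += 2.0 * float(np.log(np.einsum("cii->ci", L)).sum())
            WX = np.linalg.solve(L, grp.X)
            Wy = np.linalg.solve(L, grp.y[..., None])[..., 0]
            XtWX += np.einsum("cnp,cnq->pq", WX, WX)
            XtWy += np.einsum("cnp,cn->p", WX, Wy)
            cache.append((grp, L, WX, Wy))
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return _PD_PENALTY, None, None
        rss = 0.0
        for grp, L, WX, Wy in cache:
            r = Wy - WX @ beta
            rss += float(np.einsum("cn,cn->", r, r))
        dev = logdet + rss + self.n_obs * math.log(2 * math.pi) + penalty
        if self.spec.method == "reml":
            sign, ld = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return _PD_PENALTY, None, None
            dev += ld - self.p * math.log(2 * math.pi)
        return dev, beta, XtWX

    def deviance(self, theta: np.ndarray) -> float:
        return self.deviance_beta(theta)[0]

    def start_values(self) -> np.ndarray:
        # OLS residual scale seeds every component
        X = self.data[self.spec.x].to_numpy(dtype=float)
        y = self.data[self.spec.y].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_sd = float(np.std(y - X @ beta)) or 1.0
        theta = []
        theta += [math.log(max(resid_sd * 0.3, 1e-4))] * self.q
        if self.q and self.spec.re_structure == "unstructured":
            theta += [0.0] * (self.q * (self.q - 1) // 2)
        if self.spec.subject:
            theta.append(math.log(max(resid_sd * 0.3, 1e-4)))
        if self.spec.ar1:
            theta.append(0.0)
        theta += [math.log(max(resid_sd * 0.8, 1e-4))] * len(self.var_levels)
        return np.asarray(theta)

    def bounds(self) -> list[tuple[float, float]]:
        bounds = []
        for name in self.param_names:
            if name.startswith("log_"):
                bounds.append(_LOG_SD_BOUNDS)
            else:
                bounds.append(_ATANH_BOUNDS)
        return bounds


def fit_lmm(df: pd.DataFrame, spec: LMMSpec, start: np.ndarray | None = None,
            pins: dict[str, float] | None = None, compute_blups: bool = True) -> LMMFit:
    """Fit the mixed model by profiled maximum likelihood.

    ``pins`` fixes named covariance parameters (unconstrained scale),
    used by profile-likelihood intervals and constrained refits. On an
    unstructured random-effects failure the model is refit with a
    diagonal covariance and flagged (``boundary``/``message``).
    """
    problem = _LMMProblem(df, spec)
    theta0 = problem.start_values() if start is None else np.asarray(start, dtype=float)
    names = problem.param_names
    pin_idx = {}
    if pins:
        for k, v in pins.items():
            if k not in names:
                raise KeyError(f"unknown covariance parameter {k!r}; have {names}")
            pin_idx[names.index(k)] = float(v)
    free = [i for i in range(len(names)) if i not in pin_idx]

    def embed(tfree: np.ndarray) -> np.ndarray:
        full = np.empty(len(names))
        for i, v in pin_idx.items():
            full[i] = v
        full[free] = tfree
        return full

    fun = lambda tf: problem.deviance(embed(tf))
    bounds = [problem.bounds()[i] for i in free]
    result = None
    if free:
        # eps: finite-difference step large enough to dominate the
        # ~1e-10 relative noise of the cholesky-based deviance
        result = optimize.minimize(fun, theta0[free], method="L-BFGS-B", bounds=bounds,
                                   options={"maxiter": 500, "ftol": 1e-11,
                                            "gtol": 1e-6, "eps": 1e-5})
        converged = bool(result.success)
        message = str(result.message)
        if not converged:
            # polish past line-search trouble with a short simplex pass
            polish = optimize.minimize(fun, result.x, method="Nelder-Mead",
                                       options={"maxiter": 1200, "fatol": 1e-8,
                                                "xatol": 1e-6})
            if polish.fun <= result.fun + 1e-9:
                result = polish
                converged = True
                message = f"L-BFGS-B line search stopped; Nelder-Mead polish: {polish.message}"
        theta_hat = embed(result.x)
        if not converged and spec.re_structure == "unstructured" and len(spec.re) > 1:
            # fall back to a diagonal random-effects covariance, flagged
            diag_spec = LMMSpec(**{**spec.__dict__, "re_structure": "diagonal"})
            fit = fit_lmm(df, diag_spec, pins=pins, compute_blups=compute_blups)
            fit.message = f"unstructured fit failed ({message}); diagonal fallback"
            fit.boundary = True
            return fit
    else:
        theta_hat = embed(np.empty(0))
        converged, message = True, "all covariance parameters pinned"

    dev, beta, XtWX = problem.deviance_beta(theta_hat)
    if beta is None:
        raise ConvergenceError("deviance not finite at the optimum", result)
    cov_beta = np.linalg.inv(XtWX)
    pars = problem.unpack(theta_hat)

    # boundary detection: any log-sd at its lower bound
    at_bound = any(
        name.startswith("log_sd") and theta_hat[i] <= _LOG_SD_BOUNDS[0] + 1e-6
        for i, name in enumerate(names)
    )

    data = problem.data
    dfs = between_within_df(data, spec.x, spec.cluster, spec.subject)
    beta_s = pd.Series(beta, index=spec.x)
    se = np.sqrt(np.diag(cov_beta))
    rows = []
    for j, term in enumerate(spec.x):
        t_val = beta[j] / se[j] if se[j] > 0 else 0.0
        d = float(dfs[term])
        tcrit = stats.t.ppf(0.975, d)
        rows.append(
            {
                "term": term,
                "b": beta[j],
                "ci_lower": beta[j] - tcrit * se[j],
                "ci_upper": beta[j] + tcrit * se[j],
                "se": se[j],
                "t_value": t_val,
                "df": d,
                "p_value": 2 * stats.t.sf(abs(t_val), d),
                "r": effect_size_r(t_val, d),
            }
        )
    fixed = pd.DataFrame(rows).set_index("term")

    blups = pd.DataFrame()
    if compute_blups and (problem.q or spec.subject):
        blups = _blups(problem, pars, beta)

    G0 = pd.DataFrame(pars["G0"], index=spec.re, columns=spec.re)
    sigma2 = {lv: float(s**2) for lv, s in zip(problem.var_levels, pars["sigmas"])}
    return LMMFit(
        spec=spec,
        theta=dict(zip(names, theta_hat)),
        beta=beta_s,
        cov_beta=cov_beta,
        fixed=fixed,
        loglik=-dev / 2.0,
        deviance=dev,
        n_obs=problem.n_obs,
        n_cov_params=len(names),
        G0=G0,
        tau2=pars["tau2"],
        phi=pars["phi"],
        sigma2=sigma2,
        blups=blups,
        df_by_term=dfs,
        converged=converged,
        boundary=at_bound,
        message=message,
        problem=problem,
    )


def _blups(problem: _LMMProblem, pars, beta) -> pd.DataFrame:
    spec = problem.spec
    rows = []
    G0, tau2, phi, sigmas = pars["G0"], pars["tau2"], pars["phi"], pars["sigmas"]
    for grp in problem.groups:
        n = grp.X.shape[1]
        R = problem._resid_cov(grp, phi, sigmas)
        V = np.broadcast_to(R, (len(grp.ids), n, n)).copy()
        if problem.q:
            V += grp.Z @ G0 @ np.swapaxes(grp.Z, 1, 2)
        if tau2 is not None and grp.S is not None:
            V += tau2 * (grp.S @ grp.S.T)
        resid = grp.y - grp.X @ beta
        Vinv_r = np.linalg.solve(V, resid[..., None])[..., 0]
        if problem.q:
            b = np.einsum("qr,cnr,cn->cq", G0, grp.Z, Vinv_r)
        else:
            b = np.zeros((len(grp.ids), 0))
        for k, cid in enumerate(grp.ids):
            row = {spec.cluster: cid}
            for j, col in enumerate(spec.re):
                row[f"b({col})"] = float(b[k, j])
            rows.append(row)
    return pd.DataFrame(rows).sort_values(spec.cluster).reset_index(drop=True)


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def likelihood_ratio_test(full: LMMFit, reduced: LMMFit) -> dict:
    """LRT on nested covariance structures fit to identical rows.

    df equals the number of removed (co)variance parameters. The
    chi-square reference is used as-is; with a variance on the boundary
    this is conservative (no mixture correction is applied).
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fit to different row sets")
    if full.spec.method != reduced.spec.method:
        raise ValueError("models were fit with different likelihoods")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    ddf = full.n_cov_params - reduced.n_cov_params
    if ddf <= 0:
        raise ValueError("reduced model is not nested in the full model")
    return {
        "chi2": chi2,
        "df": ddf,
        "p_value": float(stats.chi2.sf(chi2, ddf)),
        "boundary_caveat": True,
    }


def profile_ci(fit: LMMFit, param: str, level: float = 0.95,
               expand: float = 4.0) -> tuple[float, float]:
    """Profile-likelihood CI for one covariance parameter (native scale).

    ``param`` is a covariance parameter name (``"atanh_phi"``,
    ``"log_sd(sync)"``, ...). The bound is where the profiled deviance
    rises by the chi-square(1) quantile; the returned interval is mapped
    back through tanh/exp as appropriate.
    """
    names = list(fit.theta)
    if param not in names:
        raise KeyError(f"unknown parameter {param!r}")
    crit = stats.chi2.ppf(level, 1)
    theta_hat = np.array([fit.theta[n] for n in names])
    hat = fit.theta[param]
    dev0 = fit.deviance

    def profiled(v: float) -> float:
        refit = fit_lmm(fit.problem.data, fit.spec, start=theta_hat,
                        pins={param: v}, compute_blups=False)
        return refit.deviance - dev0 - crit

    lo_bracket = hat - expand
    hi_bracket = hat + expand
    lo, hi = -np.inf, np.inf
    try:
        if profiled(lo_bracket) > 0:
            lo = optimize.brentq(profiled, lo_bracket, hat, xtol=1e-3)
        else:
            lo = lo_bracket
    except ValueError:
        lo = lo_bracket
    try:
        if profiled(hi_bracket) > 0:
            hi = optimize.brentq(profiled, hat, hi_bracket, xtol=1e-3)
        else:
            hi = hi_bracket
    except ValueError:
        hi = hi_bracket
    if param.startswith("atanh"):
        return float(np.tanh(lo)), float(np.tanh(hi))
    if param.startswith("log_sd") or param.startswith("log_sigma"):
        return float(np.exp(2 * lo)), float(np.exp(2 * hi))  # variance scale
    return float(lo), float(hi)


def _cluster_deviances(problem: _LMMProblem, theta: np.ndarray,
                       beta: np.ndarray) -> np.ndarray:
    """Per-cluster -2 log-likelihood contributions at fixed (beta, theta)."""
    pars = problem.unpack(theta)
    G0, tau2, phi, sigmas = pars["G0"], pars["tau2"], pars["phi"], pars["sigmas"]
    out = []
    order = []
    for grp in problem.groups:
        n = grp.X.shape[1]
        R = problem._resid_cov(grp, phi, sigmas)
        V = np.broadcast_to(R, (len(grp.ids), n, n)).copy()
        if problem.q:
            V += grp.Z @ G0 @ np.swapaxes(grp.Z, 1, 2)
        if tau2 is not None and grp.S is not None:
            V += tau2 * (grp.S @ grp.S.T)
        L = np.linalg.cholesky(V)
        r = grp.y - grp.X @ beta
        w = np.linalg.solve(L, r[..., None])[..., 0]
        logdet = 2.0 * np.log(np.einsum("cii->ci", L)).sum(axis=1)
        out.append(logdet + np.einsum("cn,cn->c", w, w) + n * math.log(2 * math.pi))
        order.extend(grp.ids)
    return np.concatenate(out), order


def sandwich_covariance(fit: LMMFit, step: float = 1e-5) -> pd.DataFrame:
    """Cluster-robust covariance of the joint (beta, theta) estimates.

    Under symmetric dyadic coupling the two directed series within a
    dyad are dependent in ways the working model ignores, so
    information-based standard errors undercover; the sandwich
    A^{-1} B A^{-1} with per-cluster score outer products restores
    calibration. The meat carries the J/(J-1) small-cluster correction.
    Rows/columns: fixed effects first (natural scale), then covariance
    parameters (unconstrained scale: log SDs, atanh correlations).
    """
    problem = fit.problem
    theta = np.array([fit.theta[n] for n in fit.theta])
    beta = fit.beta.to_numpy()
    k_b, k_t = len(beta), len(theta)
    x0 = np.concatenate([beta, theta])

    def devs(x):
        return _cluster_deviances(problem, x[k_b:], x[:k_b])[0]

    scale = np.maximum(np.abs(x0), 1.0) * step
    J = len(devs(x0))
    # per-cluster score of -2ll, central differences
    S = np.zeros((J, k_b + k_t))
    for i in range(k_b + k_t):
        e = np.zeros_like(x0); e[i] = scale[i]
        S[:, i] = (devs(x0 + e) - devs(x0 - e)) / (2 * scale[i])
    # total Hessian of -2ll
    H = np.zeros((k_b + k_t, k_b + k_t))
    f0 = devs(x0).sum()
    for i in range(k_b + k_t):
        ei = np.zeros_like(x0); ei[i] = scale[i]
        H[i, i] = (devs(x0 + ei).sum() - 2 * f0 + devs(x0 - ei).sum()) / scale[i] ** 2
        for j in range(i + 1, k_b + k_t):
            ej = np.zeros_like(x0); ej[j] = scale[j]
            H[i, j] = H[j, i] = (
                devs(x0 + ei + ej).sum() - devs(x0 + ei - ej).sum()
                - devs(x0 - ei + ej).sum() + devs(x0 - ei - ej).sum()
            ) / (4 * scale[i] * scale[j])
    A_inv = np.linalg.pinv(H / 2.0)
    meat = (S.T @ S) / 4.0 * (J / (J - 1))
    cov = A_inv @ meat @ A_inv
    names = list(fit.beta.index) + list(fit.theta)
    return pd.DataFrame(cov, index=names, columns=names)


def wald_theta_cov(fit: LMMFit, step: float = 1e-4) -> pd.DataFrame:
    """Covariance of the covariance-parameter estimates (unconstrained scale).

    Numeric Hessian of the profiled deviance; cov = 2 * H^{-1}. Used for
    cheap Wald intervals on tanh/exp-transformed parameters in replicate
    studies where profile intervals would be too slow.
    """
    names = list(fit.theta)
    theta = np.array([fit.theta[n] for n in names])
    k = len(theta)
    H = np.zeros((k, k))
    f0 = fit.problem.deviance(theta)

    def f(v):
        return fit.problem.deviance(v)

    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = step
            ej = np.zeros(k); ej[j] = step
            if i == j:
                val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / step**2
            else:
                val = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * step**2)
            H[i, j] = H[j, i] = val
    cov = 2.0 * np.linalg.pinv(H)
    return pd.DataFrame(cov, index=names, columns=names)
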