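"""Variance decomposition for replicated MET traits, BLUPs, broad-sense
heritability, likelihood-ratio tests of variance components, and the
fixed-effects two-way ANOVA for per-accession traits.

The mixed model is Y_ijk = mu + G_i + E_j + (GxE)_ij + eps_ijk with
independent Normal random effects. REML is computed by profiling the
residual variance and maximizing numerically over log variance ratios; the
Woodbury identity keeps every likelihood evaluation at O(q^3) in the total
number of random-effect levels q rather than the number of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RemlFit",
    "VarianceDecomposition",
    "BLUPSet",
    "reml_fit",
    "fit_met_mixed",
    "heritability",
    "lrt_component",
    "fixed_anova",
    "balanced_anova_components",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class RemlFit:
    """Generic REML fit of y = X beta + sum_k Z_k u_k + eps."""

    beta: np.ndarray
    sigma2: np.ndarray          # per random block
    sigma2_eps: float
    loglik: float               # REML log-likelihood
    blups: list[np.ndarray]     # conditional means of u_k
    converged: bool
    n_obs: int
    block_names: tuple[str, ...] = ()


def _neg2_reml(log_gamma: np.ndarray, pre: dict) -> float:
    val = _reml_internals(log_gamma, pre)[0]
    return val


def _reml_internals(log_gamma, pre):
    gamma = np.exp(np.asarray(log_gamma, dtype=float))
    q_sizes = pre["q_sizes"]
    g_diag = np.concatenate([np.full(q, g) for q, g in zip(q_sizes, gamma)])
    sg = np.sqrt(g_diag)
    # A = I + G^(1/2) Z'Z G^(1/2)
    A = pre["ZtZ"] * np.outer(sg, sg)
    A[np.diag_indices_from(A)] += 1.0
    cho = np.linalg.cholesky(A)
    logdetA = 2.0 * np.sum(np.log(np.diag(cho)))
    W = sg[:, None] * pre["ZtXy"]            # q x (p+1)
    tmp = np.linalg.solve(cho, W)
    S = pre["XytXy"] - tmp.T @ tmp           # [X y]' H^-1 [X y]
    p = pre["p"]
    XtHX = S[:p, :p]
    XtHy = S[:p, p]
    ytHy = S[p, p]
    beta = np.linalg.solve(XtHX, XtHy)
    ypy = max(ytHy - XtHy @ beta, 0.0)
    df = pre["n"] - p
    sigma2_eps = ypy / df
    sign, logdetXtHX = np.linalg.slogdet(XtHX)
    if sigma2_eps <= 0:
        sigma2_eps = np.finfo(float).tiny
    neg2 = (df * (np.log(sigma2_eps) + 1.0 + _LOG2PI) + logdetA + logdetXtHX)
    return neg2, beta, sigma2_eps, gamma, cho, sg


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    block_names: tuple[str, ...] = (),
    tol: float = 1e-8,
    max_gamma_log: float = 16.0,
) -> RemlFit:
    """REML estimation with sigma2_eps profiled out in closed form.

    Each Z_k is an n x q_k indicator (or general) design matrix for an
    i.i.d. Normal random-effect block.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    K = len(Z_list)
    Z = np.hstack(Z_list) if K else np.zeros((n, 0))
    q_sizes = [z.shape[1] for z in Z_list]
    Xy = np.column_stack([X, y])
    pre = {
        "ZtZ": Z.T @ Z,
        "ZtXy": Z.T @ Xy,
        "XytXy": Xy.T @ Xy,
        "q_sizes": q_sizes,
        "n": n,
        "p": p,
    }

    # degenerate response: no variance at all
    resid0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if np.allclose(resid0, 0.0, atol=1e-12):
        return RemlFit(
            beta=np.linalg.lstsq(X, y, rcond=None)[0],
            sigma2=np.zeros(K), sigma2_eps=0.0, loglik=np.inf,
            blups=[np.zeros(q) for q in q_sizes], converged=True,
            n_obs=n, block_names=block_names,
        )

    if K == 0:
        neg2, beta, s2e, *_ = _reml_internals(np.zeros(0), pre)
        return RemlFit(beta=beta, sigma2=np.zeros(0), sigma2_eps=s2e,
                       loglik=-0.5 * neg2, blups=[], converged=True,
                       n_obs=n, block_names=block_names)

    best = None
    for start in (np.zeros(K), np.full(K, -3.0), np.full(K, 2.0)):
        res = optimize.minimize(
            _neg2_reml, start, args=(pre,), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    lg = np.clip(best.x, -max_gamma_log, max_gamma_log)
    neg2, beta, s2e, gamma, cho, sg = _reml_internals(lg, pre)

    # BLUPs: u_hat = Gamma Z' H^-1 (y - X beta)
    Ztr = pre["ZtXy"][:, p] - pre["ZtXy"][:, :p] @ beta
    # Z'H^-1 r = Z'r - Z'Z G^(1/2) A^-1 G^(1/2) Z'r  (Woodbury)
    t1 = np.linalg.solve(cho.T, np.linalg.solve(cho, sg * Ztr))
    ZtHinv_r = Ztr - pre["ZtZ"] @ (sg * t1)
    g_diag = np.concatenate([np.full(q, g) for q, g in zip(q_sizes, gamma)])
    u_all = g_diag * ZtHinv_r
    blups, off = [], 0
    for q in q_sizes:
        blups.append(u_all[off:off + q].copy())
        off += q

    # variance ratios at the numerical floor are reported as zero
    sigma2 = gamma * s2e
    sigma2[np.exp(lg) <= np.exp(-max_gamma_log) * 1.001] = 0.0
    return RemlFit(beta=beta, sigma2=sigma2, sigma2_eps=s2e,
                   loglik=-0.5 * neg2, blups=blups,
                   converged=bool(best.success), n_obs=n,
                   block_names=block_names)


# ---------------------------------------------------------------------------
# MET-specific fitting
# ---------------------------------------------------------------------------


@dataclass
class VarianceDecomposition:
    trait: str
    grand_mean: float
    sigma2_g: float
    sigma2_e: float
    sigma2_ge: float
    sigma2_eps: float
    H2: float | None = None
    lrt: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True

    @property
    def percent_of_total(self) -> dict[str, float]:
        total = self.sigma2_g + self.sigma2_e + self.sigma2_ge + self.sigma2_eps
        if total == 0:
            return {k: 0.0 for k in ("g", "e", "ge", "eps")}
        return {
            "g": 100.0 * self.sigma2_g / total,
            "e": 100.0 * self.sigma2_e / total,
            "ge": 100.0 * self.sigma2_ge / total,
            "eps": 100.0 * self.sigma2_eps / total,
        }


@dataclass
class BLUPSet:
    accessions: list[str]
    environments: list[str]
    blup_g: pd.Series          # indexed by accession
    blup_ge: pd.DataFrame      # accession x environment


def _newton_refine(f, x0: np.ndarray, f0: float, steps: int = 4,
                   h: float = 1e-4) -> tuple[np.ndarray, float]:
    """A few damped Newton steps with central-difference derivatives; sharpens
    an optimizer solution well below its f-tolerance resolution."""
    x, fx = x0.copy(), f0
    k = len(x)
    for _ in range(steps):
        grad = np.zeros(k)
        hess = np.zeros((k, k))
        fp = np.zeros(k)
        fm = np.zeros(k)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            fp[i] = f(x + ei)
            fm[i] = f(x - ei)
            grad[i] = (fp[i] - fm[i]) / (2 * h)
            hess[i, i] = (fp[i] - 2 * fx + fm[i]) / h**2
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h
                ej[j] = h
                fpp = f(x + ei + ej)
                hess[i, j] = hess[j, i] = (fpp - fp[i] - fp[j] + fx) / h**2
        try:
            evals = np.linalg.eigvalsh(hess)
            if evals.min() <= 1e-10:
                break
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # near the optimum f-differences sit at the noise floor, so accept
        # small PD-Hessian Newton steps unconditionally (trust radius 0.1)
        norm = np.linalg.norm(step)
        if norm > 0.1:
            fc = f(x - step)
            if fc > fx:
                break
            fx = fc
        x = x - step
        if norm < 1e-10:
            break
    fx = min(fx, f(x))
    return x, fx


def _met_reml(
    ybar: np.ndarray,
    kvec: np.ndarray,
    sse_within: float,
    n_total: int,
    X_cell: np.ndarray,
    Z_cells: list[np.ndarray],
    cell_diag: bool,
    block_names: tuple[str, ...] = (),
    tol: float = 1e-12,
) -> RemlFit:
    """Exact REML for models with an i.i.d. residual and (optionally) a
    per-cell random effect, after collapsing replicates to cell means.

    The observation-level likelihood factorizes into a within-cell part
    (sse_within ~ sigma2_eps * chi2) and a cell-mean part in which the
    per-cell random effect contributes a diagonal gamma*k_c term; every
    evaluation then costs O(C q^2) for q total non-diagonal levels.
    """
    C = len(ybar)
    sqrtk = np.sqrt(kvec.astype(float))
    Xs = sqrtk[:, None] * np.atleast_2d(X_cell)
    ys = sqrtk * ybar
    B = np.hstack([sqrtk[:, None] * Z for Z in Z_cells]) if Z_cells else np.zeros((C, 0))
    q_sizes = [Z.shape[1] for Z in Z_cells]
    p = Xs.shape[1]
    df = n_total - p
    M = np.column_stack([Xs, ys])
    K = len(Z_cells)
    npar = K + int(cell_diag)

    # degenerate: zero residual variation everywhere
    ls_beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
    if sse_within <= 1e-300 and np.allclose(ys - Xs @ ls_beta, 0.0, atol=1e-12):
        return RemlFit(beta=ls_beta, sigma2=np.zeros(npar), sigma2_eps=0.0,
                       loglik=np.inf, blups=[np.zeros(q) for q in q_sizes]
                       + ([np.zeros(C)] if cell_diag else []),
                       converged=True, n_obs=n_total, block_names=block_names)

    def internals(log_gamma):
        gam = np.exp(np.asarray(log_gamma, dtype=float))
        g_blocks = gam[:K]
        d = 1.0 + gam[K] * kvec if cell_diag else np.ones(C)
        sg = np.concatenate([np.full(q, np.sqrt(g)) for q, g in zip(q_sizes, g_blocks)]) \
            if K else np.zeros(0)
        Bd = B / d[:, None]
        A = (B.T @ Bd) * np.outer(sg, sg)
        A[np.diag_indices_from(A)] += 1.0
        cho = np.linalg.cholesky(A)
        BdM = sg[:, None] * (B.T @ (M / d[:, None]))
        T = np.linalg.solve(cho, BdM)
        S = M.T @ (M / d[:, None]) - T.T @ T
        XtHX = S[:p, :p]
        beta = np.linalg.solve(XtHX, S[:p, p])
        ypy = max(S[p, p] - S[:p, p] @ beta, 0.0) + sse_within
        s2e = max(ypy / df, np.finfo(float).tiny)
        _, logdetX = np.linalg.slogdet(XtHX)
        neg2 = (df * (np.log(s2e) + 1.0 + _LOG2PI) + np.log(d).sum()
                + 2.0 * np.log(np.diag(cho)).sum() + logdetX)
        return neg2, beta, s2e, gam, cho, sg, d

    def neg2f(lg):
        return internals(lg)[0]

    if npar == 0:
        neg2, beta, s2e, *_ = internals(np.zeros(0))
        return RemlFit(beta=beta, sigma2=np.zeros(0), sigma2_eps=s2e,
                       loglik=-0.5 * neg2, blups=[], converged=True,
                       n_obs=n_total, block_names=block_names)

    # L-BFGS-B gets close cheaply; Nelder-Mead polishes to high precision.
    best = None
    for start in (np.zeros(npar), np.full(npar, -4.0)):
        res = optimize.minimize(neg2f, start, method="L-BFGS-B",
                                bounds=[(-18.0, 18.0)] * npar)
        if best is None or res.fun < best.fun - 1e-13:
            best = res
    polish = optimize.minimize(neg2f, best.x, method="Nelder-Mead",
                               options={"xatol": 1e-4, "fatol": tol,
                                        "maxiter": 300, "maxfev": 300})
    if polish.fun <= best.fun:
        best = polish
    x, fx = _newton_refine(neg2f, np.asarray(best.x, float), best.fun)
    lg = np.clip(x, -18.0, 18.0)
    neg2, beta, s2e, gam, cho, sg, d = internals(lg)

    r = ys - Xs @ beta
    hr = r / d
    if K:
        t = np.linalg.solve(cho.T, np.linalg.solve(cho, sg * (B.T @ hr)))
        hinv_r = hr - (B @ (sg * t)) / d
    else:
        hinv_r = hr
    blups, off = [], 0
    bu = B.T @ hinv_r
    for q, g in zip(q_sizes, gam[:K]):
        blups.append(g * bu[off:off + q])
        off += q
    if cell_diag:
        blups.append(gam[K] * sqrtk * hinv_r)

    sigma2 = gam * s2e
    sigma2[lg <= -17.9] = 0.0
    return RemlFit(beta=beta, sigma2=sigma2, sigma2_eps=s2e,
                   loglik=-0.5 * neg2, blups=blups,
                   converged=bool(best.success), n_obs=n_total,
                   block_names=block_names)


def _designs(df: pd.DataFrame):
    acc = pd.Categorical(df["accession"].astype(str))
    env = pd.Categorical(df["environment"].astype(str))
    n = len(df)
    Zg = np.zeros((n, len(acc.categories)))
    Zg[np.arange(n), acc.codes] = 1.0
    Ze = np.zeros((n, len(env.categories)))
    Ze[np.arange(n), env.codes] = 1.0
    cell = acc.codes.astype(int) * len(env.categories) + env.codes.astype(int)
    present = np.unique(cell)
    cell_map = {c: i for i, c in enumerate(present)}
    Zge = np.zeros((n, len(present)))
    Zge[np.arange(n), [cell_map[c] for c in cell]] = 1.0
    return acc, env, Zg, Ze, Zge, present


def fit_met_mixed(met, trait: str, lrt: bool = True,
                  boundary_mixture: bool = False, blups: bool = True):
    """Fit the MET mixed model for a replicated quantitative trait.

    Returns (VarianceDecomposition, BLUPSet). Variance components come from
    the all-random parametrization (mu fixed; G, E, GxE random); BLUPs come
    from the environment-fixed parametrization (mu + E fixed; G, GxE
    random), matching the two runs described for the published analysis.
    """
    spec = met.trait_specs.get(trait)
    if spec is not None and spec.kind != "replicated_quantitative":
        raise ValueError(f"trait {trait!r} is not replicated_quantitative")
    df = met.trait(trait).dropna(subset=["value"])
    if df["environment"].nunique() < 2:
        raise ValueError("need >= 2 environments")
    if df["accession"].nunique() < 2:
        raise ValueError("need >= 2 accessions")
    grp = df.groupby(["accession", "environment"], sort=True)["value"]
    cells = grp.agg(["mean", "count"]).reset_index()
    ybar = cells["mean"].to_numpy(dtype=float)
    kvec = cells["count"].to_numpy(dtype=float)
    sse_w = float((grp.var(ddof=1).fillna(0.0) * (kvec - 1).clip(min=0)).sum())
    n_total = int(kvec.sum())
    acc = pd.Categorical(cells["accession"].astype(str))
    env = pd.Categorical(cells["environment"].astype(str))
    C = len(cells)
    Zg = np.zeros((C, len(acc.categories)))
    Zg[np.arange(C), acc.codes] = 1.0
    Ze = np.zeros((C, len(env.categories)))
    Ze[np.arange(C), env.codes] = 1.0
    ones = np.ones((C, 1))

    full = _met_reml(ybar, kvec, sse_w, n_total, ones, [Zg, Ze],
                     cell_diag=True, block_names=("g", "e", "ge"))
    vc = VarianceDecomposition(
        trait=trait, grand_mean=float(full.beta[0]),
        sigma2_g=float(full.sigma2[0]), sigma2_e=float(full.sigma2[1]),
        sigma2_ge=float(full.sigma2[2]), sigma2_eps=float(full.sigma2_eps),
        converged=full.converged,
    )
    vc.H2 = heritability(vc)

    if lrt and np.isfinite(full.loglik):
        drops = {"g": ([Ze], True), "e": ([Zg], True), "ge": ([Zg, Ze], False)}
        for name, (zlist, diag) in drops.items():
            red = _met_reml(ybar, kvec, sse_w, n_total, ones, zlist, cell_diag=diag)
            vc.lrt[name] = lrt_component(full, red,
                                         boundary_mixture=boundary_mixture)

    if not blups:
        return vc, None

    # environment-fixed parametrization for BLUP extraction
    Xenv = np.column_stack([ones, Ze[:, 1:]])
    bfit = _met_reml(ybar, kvec, sse_w, n_total, Xenv, [Zg],
                     cell_diag=True, block_names=("g", "ge"))
    accs = list(acc.categories)
    envs = list(env.categories)
    blup_g = pd.Series(bfit.blups[0], index=accs, name="blup_g")
    ge_mat = np.zeros((len(accs), len(envs)))
    ge_mat[acc.codes, env.codes] = bfit.blups[1]
    blup_ge = pd.DataFrame(ge_mat, index=accs, columns=envs)
    return vc, BLUPSet(accs, envs, blup_g, blup_ge)


def heritability(vc: VarianceDecomposition) -> float | None:
    """Broad-sense heritability across environments; the environment main
    variance is deliberately excluded from the denominator."""
    denom = vc.sigma2_g + vc.sigma2_ge + vc.sigma2_eps
    if denom <= 0:
        return None
    return vc.sigma2_g / denom


def lrt_component(full: RemlFit | VarianceDecomposition, reduced: RemlFit,
                  boundary_mixture: bool = False) -> tuple[float, float]:
    """LRT of one variance component: 2*(l_full - l_reduced) vs chi2(1).

    By default the p-value is the plain one-df chi-square tail (the
    published "two-tailed chi^2, one df" procedure); ``boundary_mixture``
    switches to the 0.5*chi2_0 + 0.5*chi2_1 boundary-correct mixture.
    """
    if isinstance(full, RemlFit) and isinstance(reduced, RemlFit):
        if full.n_obs != reduced.n_obs:
            raise ValueError("fits use different observation sets")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    if not np.isfinite(stat):
        return float("nan"), float("nan")
    p = float(stats.chi2.sf(stat, 1))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return float(stat), p


def balanced_anova_components(met, trait: str) -> dict[str, float]:
    """Method-of-moments (expected mean squares) estimator for a balanced
    g x e x k design; equals REML when all estimates are interior."""
    df = met.trait(trait)
    wide = df.pivot_table(index="accession", columns="environment",
                          values="value", aggfunc=list)
    g = wide.shape[0]
    e = wide.shape[1]
    counts = df.groupby(["accession", "environment"]).size()
    if counts.nunique() != 1:
        raise ValueError("design is not balanced")
    k = int(counts.iloc[0])
    y = df["value"].to_numpy(dtype=float)
    cell = df.groupby(["accession", "environment"])["value"].mean()
    acc_mean = df.groupby("accession")["value"].mean()
    env_mean = df.groupby("environment")["value"].mean()
    grand = y.mean()
    ss_g = e * k * ((acc_mean - grand) ** 2).sum()
    ss_e = g * k * ((env_mean - grand) ** 2).sum()
    cellv = cell.reset_index()
    cellv["exp"] = (acc_mean[cellv["accession"]].to_numpy()
                    + env_mean[cellv["environment"]].to_numpy() - grand)
    ss_ge = k * ((cellv["value"] - cellv["exp"]) ** 2).sum()
    merged = df.merge(cell.rename("cellmean"), on=["accession", "environment"])
    ss_eps = ((merged["value"] - merged["cellmean"]) ** 2).sum()
    ms_g = ss_g / (g - 1)
    ms_e = ss_e / (e - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ms_eps = ss_eps / (g * e * (k - 1)) if k > 1 else 0.0
    return {
        "sigma2_eps": ms_eps,
        "sigma2_ge": max((ms_ge - ms_eps) / k, 0.0),
        "sigma2_g": max((ms_g - ms_ge) / (e * k), 0.0),
        "sigma2_e": max((ms_e - ms_ge) / (g * k), 0.0),
    }


def fixed_anova(met, trait: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type-III fixed-effects two-way ANOVA (no interaction) for
    accession-mean traits; also returns the accession x environment mean
    table for interaction plotting."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = met.trait(trait).dropna(subset=["value"]).copy()
    df["value"] = pd.to_numeric(df["value"])
    if df["accession"].nunique() < 2 or df["environment"].nunique() < 2:
        raise ValueError("need >= 2 levels of accession and environment")
    if df["value"].nunique() == 1:
        tab = pd.DataFrame(
            {"sum_sq": [0.0, 0.0, 0.0], "df": [np.nan] * 3,
             "F": [0.0, 0.0, np.nan], "PR(>F)": [1.0, 1.0, np.nan]},
            index=["C(accession, Sum)", "C(environment, Sum)", "Residual"],
        )
    else:
        model = smf.ols(
            "value ~ C(accession, Sum) + C(environment, Sum)", data=df
        ).fit()
        tab = sm.stats.anova_lm(model, typ=3).drop(index="Intercept")
        tab["PR(>F)"] = tab["PR(>F)"].fillna(1.0)
    cell_means = (df.groupby(["accession", "environment"])["value"]
                  .mean().reset_index())
    return tab, cell_means
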