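"""Bayesian Gaussian linear mixed-effects models via blocked Gibbs sampling.

The analysis models are random-intercept LMEs:

    y = X b + sum_g Z_g u_g + e,   u_g ~ N(0, s2_g I),   e ~ N(0, s2_e I)

with diffuse priors: b ~ N(0, 1e8 I), variance components ~
inverse-gamma(0.001, 0.001).  All full conditionals are conjugate, so the
sampler is a blocked Gibbs scheme: b | rest is Gaussian, each
random-intercept vector | rest is Gaussian (diagonal precision for
intercepts), each variance component | rest is inverse-gamma.

Defaults follow common practice for these models: 13 000 iterations,
3 000 burn-in, thinning 10, retaining exactly 1 000 draws.  Effects are
summarized by the posterior mean, the 95% highest density interval
(shortest interval containing 95% of draws), and the two-sided tail
probability pMCMC = 2·max(1, min(#draws>0, #draws<0))/N; an effect is
flagged significant when 0 is outside the HDI and pMCMC < 0.05.

A bivariate extension shares the random-intercept structure across two
responses and samples their residual covariance from its conditional
inverse-Wishart, yielding a posterior for the residual correlation — the
multivariate-multilevel route to correlations between outcomes measured
on the same units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Table of analysis-model layouts: response column, fixed factors that
#: enter with all mutual interactions, additive covariates, and random
#: intercept groupings.  `phase_segment` is the 9-level crossing of
#: scenario phase with first/middle/last minute.
MODEL_TABLE: dict[int, dict] = {
    1: dict(fixed=["phase", "role", "difficulty"], additive=["experience"],
            random=["participant", "team", "scenario"]),
    2: dict(fixed=["phase_segment", "role", "difficulty"], additive=["experience"],
            random=["participant", "team", "scenario"]),
    3: dict(fixed=["phase", "difficulty"], additive=["experience"],
            random=["participant", "team", "scenario"]),
    4: dict(fixed=["role", "difficulty"], additive=["experience"],
            random=["participant", "team", "scenario"]),
    5: dict(fixed=["phase", "difficulty"], additive=["experience"],
            random=["team", "scenario"]),
    6: dict(fixed=["phase_segment", "difficulty"], additive=["experience"],
            random=["team", "scenario"]),
}

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "phase": ("single_provider", "team", "debriefing"),
    "difficulty": ("low", "medium", "high"),
    "role": ("initial_provider", "responder"),
    "experience": ("Y1", "Y2", "Y3", "attending"),
    "segment": ("first_minute", "middle_minute", "last_minute"),
}
FACTOR_LEVELS["phase_segment"] = tuple(
    f"{p}:{s}" for p in FACTOR_LEVELS["phase"] for s in FACTOR_LEVELS["segment"]
)


@dataclass
class McmcSettings:
    iterations: int = 13000
    burnin: int = 3000
    thin: int = 10
    seed: int = 0
    beta_prior_var: float = 1e8
    vc_prior_shape: float = 0.001
    vc_prior_scale: float = 0.001

    def __post_init__(self) -> None:
        if min(self.iterations, self.thin) < 1 or self.burnin < 0:
            raise ValueError("MCMC settings must be positive")
        if self.burnin >= self.iterations:
            raise ValueError("burn-in must be shorter than the chain")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass
class LmeDesign:
    """A realized design: fixed-effect matrix plus random-intercept codes."""

    model_id: int | None
    response: str
    X: np.ndarray
    coef_names: list[str]
    groups: dict[str, np.ndarray]  # name -> integer codes, 0..n_levels-1
    group_levels: dict[str, list] = field(default_factory=dict)


@dataclass
class PosteriorSamples:
    draws: pd.DataFrame  # retained draws x named parameters

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    @property
    def n_draws(self) -> int:
        return len(self.draws)


@dataclass
class EffectSummary:
    parameter: str
    b: float
    hdi95: tuple[float, float]
    pmcmc: float

    @property
    def significant(self) -> bool:
        lo, hi = self.hdi95
        return (not lo <= 0 <= hi) and self.pmcmc < 0.05


@dataclass
class CorrelationSummary:
    r: float
    hdi95: tuple[float, float]

    @property
    def significant(self) -> bool:
        lo, hi = self.hdi95
        return not lo <= 0 <= hi


def successive_difference_contrasts(k: int) -> np.ndarray:
    """Backward-difference coding: contrast j estimates level j+1 − level j.

    Returns a (k, k-1) matrix of codes (rows: levels, columns: contrasts).
    """
    C = np.zeros((k, k - 1))
    for j in range(k - 1):
        C[: j + 1, j] = -(k - j - 1) / k
        C[j + 1 :, j] = (j + 1) / k
    return C


def _code_factor(values: pd.Series, name: str, coding: str) -> tuple[np.ndarray, list[str]]:
    levels = list(FACTOR_LEVELS.get(name, sorted(values.unique())))
    present = [lv for lv in levels if lv in set(values)]
    if len(present) < 2:
        import warnings

        warnings.warn(f"factor {name!r} has a single level; dropped", stacklevel=2)
        return np.empty((len(values), 0)), []
    idx = pd.Categorical(values, categories=present).codes
    if np.any(idx < 0):
        raise ValueError(f"unknown level in factor {name!r}")
    k = len(present)
    if coding == "successive_difference":
        C = successive_difference_contrasts(k)
        names = [f"{name}[{present[j + 1]}-{present[j]}]" for j in range(k - 1)]
    elif coding == "treatment":
        C = np.vstack([np.zeros((1, k - 1)), np.eye(k - 1)])
        names = [f"{name}[{lv}]" for lv in present[1:]]
    else:
        raise ValueError(f"unknown coding {coding!r}")
    return C[idx], names


def build_design(
    model_id: int,
    data: pd.DataFrame,
    response: str,
    coding: str = "successive_difference",
) -> LmeDesign:
    """Build design matrices for one of the six analysis-model layouts.

    Fixed factors listed for the model enter with *all* mutual
    interactions (products of their contrast columns); the experience
    covariate enters additively.  Three-level factors use
    successive-difference coding by default (so coefficients read as
    adjacent-level differences, e.g. team − single_provider); treatment
    coding is available via ``coding``.  Random intercepts are returned
    as integer group codes per grouping factor.

    Raises if the resulting fixed-effect matrix is rank deficient (for
    example an empty design cell).
    """
    spec = MODEL_TABLE[model_id]
    if "phase_segment" in spec["fixed"] and "phase_segment" not in data:
        data = data.assign(phase_segment=data["phase"] + ":" + data["segment"])

    blocks: list[np.ndarray] = [np.ones((len(data), 1))]
    names: list[str] = ["(Intercept)"]

    coded: dict[str, tuple[np.ndarray, list[str]]] = {}
    for f in spec["fixed"]:
        coded[f] = _code_factor(data[f], f, coding)

    factors = [f for f in spec["fixed"] if coded[f][0].shape[1] > 0]
    # main effects then all interaction orders
    from itertools import combinations

    for order in range(1, len(factors) + 1):
        for combo in combinations(factors, order):
            M = np.ones((len(data), 1))
            nm = [""]
            for f in combo:
                Cf, names_f = coded[f]
                M = np.concatenate(
                    [M[:, [i]] * Cf for i in range(M.shape[1])], axis=1
                )
                nm = [f"{a}:{b}" if a else b for a in nm for b in names_f]
            blocks.append(M)
            names.extend(nm)

    for cov in spec["additive"]:
        if cov in data:
            Cc, names_c = _code_factor(data[cov], cov, "treatment")
            blocks.append(Cc)
            names.extend(names_c)

    X = np.concatenate(blocks, axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]} columns); "
            "check for empty factor cells"
        )

    groups: dict[str, np.ndarray] = {}
    group_levels: dict[str, list] = {}
    for g in spec["random"]:
        cat = pd.Categorical(data[g])
        if len(cat.categories) < 2:
            raise ValueError(f"random grouping {g!r} needs >= 2 levels")
        groups[g] = np.asarray(cat.codes)
        group_levels[g] = list(cat.categories)

    return LmeDesign(model_id, response, X, names, groups, group_levels)


def fit_gibbs(
    y: np.ndarray,
    design: LmeDesign,
    settings: McmcSettings | None = None,
) -> PosteriorSamples:
    """Blocked Gibbs sampler for the random-intercept Gaussian LME.

    Deterministic given ``settings.seed``.  Returns the retained draws
    of the fixed effects and each variance component (``sigma2_<group>``
    and ``sigma2_resid``).
    """
    settings = settings or McmcSettings()
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X = design.X
    n, p = X.shape
    if y.size != n:
        raise ValueError("response length does not match design")
    rng = np.random.default_rng(settings.seed)

    group_names = list(design.groups)
    codes = [design.groups[g] for g in group_names]
    n_levels = [c.max() + 1 for c in codes]
    counts = [np.bincount(c, minlength=q).astype(float) for c, q in zip(codes, n_levels)]

    XtX = X.T @ X
    prior_prec = np.eye(p) / settings.beta_prior_var
    a0, b0 = settings.vc_prior_shape, settings.vc_prior_scale

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u = [np.zeros(q) for q in n_levels]
    s2_g = [1.0] * len(group_names)
    s2_e = max(float(np.var(y - X @ beta)), 1e-6)

    keep = settings.n_retained
    out = np.empty((keep, p + len(group_names) + 1))
    kept = 0

    for it in range(settings.iterations):
        # beta | rest
        resid = y.copy()
        for c, ug in zip(codes, u):
            resid -= ug[c]
        prec = XtX / s2_e + prior_prec
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, X.T @ resid / s2_e)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)

        # each random-intercept vector | rest (diagonal conditional)
        fitted_fixed = X @ beta
        for g in range(len(group_names)):
            resid = y - fitted_fixed
            for h, (c, ug) in enumerate(zip(codes, u)):
                if h != g:
                    resid -= ug[c]
            sums = np.bincount(codes[g], weights=resid, minlength=n_levels[g])
            var = 1.0 / (counts[g] / s2_e + 1.0 / s2_g[g])
            mean_u = var * sums / s2_e
            u[g] = mean_u + np.sqrt(var) * rng.standard_normal(n_levels[g])

            # sigma2_g | u_g
            shape = a0 + n_levels[g] / 2
            scale = b0 + 0.5 * float(u[g] @ u[g])
            s2_g[g] = scale / rng.gamma(shape)

        # sigma2_e | rest
        resid = y - fitted_fixed
        for c, ug in zip(codes, u):
            resid -= ug[c]
        s2_e = (b0 + 0.5 * float(resid @ resid)) / rng.gamma(a0 + n / 2)

        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            if kept < keep:
                out[kept, :p] = beta
                out[kept, p : p + len(group_names)] = s2_g
                out[kept, -1] = s2_e
                kept += 1

    cols = design.coef_names + [f"sigma2_{g}" for g in group_names] + ["sigma2_resid"]
    return PosteriorSamples(pd.DataFrame(out[:kept], columns=cols))


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    m = int(np.ceil(mass * n))  # draws inside the interval
    if m >= n:
        return (float(x[0]), float(x[-1]))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return (float(x[i]), float(x[i + m - 1]))


def pmcmc(draws: np.ndarray) -> float:
    """Two-sided MCMC tail probability, floored at 2/N for finite chains."""
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    tail = min((x > 0).sum(), (x < 0).sum())
    return min(1.0, 2.0 * max(1, int(tail)) / n)


def summarize_effect(samples: PosteriorSamples, parameter: str) -> EffectSummary:
    draws = samples[parameter]
    if draws.size < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    return EffectSummary(
        parameter=parameter,
        b=float(draws.mean()),
        hdi95=hdi(draws),
        pmcmc=pmcmc(draws),
    )


def summarize_all(samples: PosteriorSamples) -> pd.DataFrame:
    rows = []
    for name in samples.draws.columns:
        s = summarize_effect(samples, name)
        rows.append(
            dict(parameter=name, b=s.b, hdi_lo=s.hdi95[0], hdi_hi=s.hdi95[1],
                 pmcmc=s.pmcmc, significant=s.significant)
        )
    return pd.DataFrame(rows)


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a single chain."""
    x = np.asarray(draws, dtype=float).ravel()
    half = x.size // 2
    chains = np.stack([x[:half], x[half : 2 * half]])
    m, n = chains.shape
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (n * w)))


def effective_sample_size(draws: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
    rho_sum = 0.0
    for k in range(1, n):
        if acf[k] < 0:
            break
        rho_sum += acf[k]
    return float(n / (1 + 2 * rho_sum))


def check_convergence(
    samples: PosteriorSamples, rhat_max: float = 1.05, ess_min: float = 200
) -> dict[str, bool]:
    """Per-parameter convergence flags (split-R̂ and effective sample size)."""
    report = {}
    for name in samples.draws.columns:
        d = samples[name]
        report[name] = split_rhat(d) < rhat_max and effective_sample_size(d) > ess_min
    return report


def fit_bivariate_correlation(
    y1: np.ndarray,
    y2: np.ndarray,
    design: LmeDesign,
    settings: McmcSettings | None = None,
) -> CorrelationSummary:
    """Residual correlation between two responses sharing one design.

    A bivariate Gaussian mixed model: each response gets its own fixed
    effects and random intercepts (built from the same design), and the
    2×2 residual covariance is sampled from its conditional
    inverse-Wishart.  The summary is the posterior of the residual
    correlation with its 95% HDI.
    """
    settings = settings or McmcSettings()
    y1 = np.asarray(y1, float).ravel()
    y2 = np.asarray(y2, float).ravel()
    ok = np.isfinite(y1) & np.isfinite(y2)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 complete response pairs")
    Y = np.column_stack([y1[ok], y2[ok]])
    X = design.X[ok]
    codes_full = {g: design.groups[g][ok] for g in design.groups}
    n, p = X.shape
    rng = np.random.default_rng(settings.seed)

    group_names = list(codes_full)
    codes = [pd.Categorical(codes_full[g]).codes for g in group_names]
    n_levels = [c.max() + 1 for c in codes]
    counts = [np.bincount(c, minlength=q).astype(float) for c, q in zip(codes, n_levels)]

    XtX = X.T @ X
    prior_prec = np.eye(p) / settings.beta_prior_var
    a0, b0 = settings.vc_prior_shape, settings.vc_prior_scale
    nu0, S0 = 3.0, np.eye(2) * 0.001  # weak inverse-Wishart for the 2x2 residual cov

    beta = np.linalg.lstsq(X, Y, rcond=None)[0]  # p x 2
    u = [np.zeros((q, 2)) for q in n_levels]
    s2_g = [np.ones(2) for _ in group_names]
    Sigma = np.cov((Y - X @ beta).T) + np.eye(2) * 1e-6

    keep = settings.n_retained
    r_draws = np.empty(keep)
    kept = 0

    for it in range(settings.iterations):
        Sigma_inv = np.linalg.inv(Sigma)
        # conditional regressions: response j given the other's residual
        for j in range(2):
            k = 1 - j
            resid_k = Y[:, k] - X @ beta[:, k]
            for c, ug in zip(codes, u):
                resid_k = resid_k - ug[c, k]
            slope = Sigma[j, k] / Sigma[k, k]
            cond_var = Sigma[j, j] - Sigma[j, k] ** 2 / Sigma[k, k]
            offset = slope * resid_k

            # beta_j | rest
            resid = Y[:, j] - offset
            for c, ug in zip(codes, u):
                resid = resid - ug[c, j]
            prec = XtX / cond_var + prior_prec
            mean = np.linalg.solve(prec, X.T @ resid / cond_var)
            L = np.linalg.cholesky(prec)
            beta[:, j] = mean + np.linalg.solve(L.T, rng.standard_normal(p))

            # random intercepts for response j
            fitted = X @ beta[:, j] + offset
            for g in range(len(group_names)):
                resid = Y[:, j] - fitted
                for h, (c, ug) in enumerate(zip(codes, u)):
                    if h != g:
                        resid = resid - ug[c, j]
                sums = np.bincount(codes[g], weights=resid, minlength=n_levels[g])
                var = 1.0 / (counts[g] / cond_var + 1.0 / s2_g[g][j])
                u[g][:, j] = var * sums / cond_var + np.sqrt(var) * rng.standard_normal(
                    n_levels[g]
                )
                shape = a0 + n_levels[g] / 2
                scale = b0 + 0.5 * float(u[g][:, j] @ u[g][:, j])
                s2_g[g][j] = scale / rng.gamma(shape)

        # residual covariance | rest
        E = Y - X @ beta
        for c, ug in zip(codes, u):
            E = E - ug[c]
        Sn = S0 + E.T @ E
        Sigma = _inv_wishart(rng, nu0 + n, Sn)

        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            if kept < keep:
                r_draws[kept] = Sigma[0, 1] / np.sqrt(Sigma[0, 0] * Sigma[1, 1])
                kept += 1

    r_draws = r_draws[:kept]
    return CorrelationSummary(r=float(r_draws.mean()), hdi95=hdi(r_draws))


def _inv_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from inverse-Wishart(df, scale) via the Wishart of the inverse."""
    d = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = L @ A @ A.T @ L.T  # Wishart(df, scale^-1)
    return np.linalg.inv(W)
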