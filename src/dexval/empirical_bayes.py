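"""Hierarchical / empirical-Bayes selectors.

Three ingredients are combined here:

* classical one-sided p-values (paired/two-sample t, and Wilcoxon
  signed-rank / rank-sum);
* a moderated t-statistic: gene variances are modelled as draws from a
  scaled inverse-chi-square prior with ``d0`` degrees of freedom and
  scale ``s0^2``; the hyperparameters are estimated by matching the first
  two moments of ``log s_i^2`` to the implied scaled-F distribution
  (digamma/trigamma moment equations), and each gene's variance is shrunk
  to the posterior value ``s~^2 = (d0 s0^2 + df s^2) / (d0 + df)``;
* a local false discovery rate: one-sided p-values are mapped to z-scores
  ``z = Phi^{-1}(1 - p)``, the marginal density ``f(z)`` is fit by Poisson
  regression of binned counts on a natural-spline basis, and
  ``fdr(z) = min(1, pi0 f0(z) / f(z))`` with ``f0`` either the theoretical
  standard normal or an empirical null fitted on the central z-interval.

The moderated-t posterior-odds selector estimates the null proportion
``pi(H0)`` by fixed-point iteration of the mean posterior null
probability, starting at 0.9 and stopping when the update moves by less
than 1/1000 or the difference changes sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import patsy
import statsmodels.api as sm
from scipy import special, stats

from .datamodel import GroupedExpression
from .foldchange import estimate_dhat

__all__ = [
    "PValueVector",
    "ModeratedTFit",
    "LogOddsState",
    "LocalFdrFit",
    "t_pvalues",
    "wilcoxon_pvalues",
    "fit_moderated_t",
    "iterate_pi0",
    "limma_prob",
    "local_fdr",
    "eb_selector",
    "EB_VARIANTS",
]

EB_VARIANTS = (
    "t_locfdr",
    "wilcoxon_locfdr",
    "modt_locfdr",
    "t_empnull",
    "wilcoxon_empnull",
    "modt_limma",
)

_P_CLIP = 1e-12


@dataclass
class PValueVector:
    p: np.ndarray
    sidedness: str = "one-sided"
    test: str = "t"


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def _paired_stats(data: GroupedExpression):
    d = data.differences()
    valid = ~np.isnan(d)
    n_i = valid.sum(axis=1)
    ok = n_i >= 2
    dbar = np.where(ok, np.nansum(np.where(valid, d, 0.0), axis=1) / np.maximum(n_i, 1), np.nan)
    ss = np.sum(np.where(valid, d - dbar[:, None], 0.0) ** 2, axis=1)
    s2 = np.where(ok, ss / np.maximum(n_i - 1, 1), np.nan)
    return dbar, s2, n_i


def _group_stats(a: np.ndarray):
    valid = ~np.isnan(a)
    n = valid.sum(axis=1)
    mean = np.where(n > 0, np.nansum(np.where(valid, a, 0.0), axis=1) / np.maximum(n, 1), np.nan)
    ss = np.sum(np.where(valid, a - mean[:, None], 0.0) ** 2, axis=1)
    return mean, ss, n


def t_pvalues(data: GroupedExpression) -> PValueVector:
    """One-sided (upper-tail) paired or equal-variance two-sample t p-values."""
    if data.paired:
        dbar, s2, n_i = _paired_stats(data)
        df = n_i - 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = dbar / np.sqrt(s2 / n_i)
    else:
        xbar, ssx, n = _group_stats(data.control)
        xpbar, ssxp, nprime = _group_stats(data.treatment)
        ok = (n >= 2) & (nprime >= 2)
        df = np.where(ok, n + nprime - 2.0, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = (ssx + ssxp) / df
            tstat = (xpbar - xbar) / np.sqrt(sp2 * (1.0 / n + 1.0 / nprime))
    degenerate = np.isfinite(df) & ~np.isfinite(tstat)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} gene(s) with zero variance: p masked")
    with np.errstate(invalid="ignore"):
        p = stats.t.sf(tstat, df)
    return PValueVector(np.where(np.isfinite(tstat), p, np.nan), test="t")


def wilcoxon_pvalues(data: GroupedExpression) -> PValueVector:
    """One-sided signed-rank (paired) or rank-sum (unpaired) p-values.

    Exact null distributions are used for small samples without ties
    (scipy's automatic method selection); zero paired differences are
    dropped before ranking.
    """
    m = data.m
    p = np.full(m, np.nan)
    if data.paired:
        d = data.differences()
        for i in range(m):
            di = d[i][~np.isnan(d[i])]
            di = di[di != 0.0]
            if di.size == 0:
                continue
            try:
                p[i] = stats.wilcoxon(di, alternative="greater").pvalue
            except ValueError:
                continue
        degenerate = np.isnan(p)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} gene(s) with all-zero differences masked"
            )
    else:
        for i in range(m):
            xi = data.control[i][~np.isnan(data.control[i])]
            xpi = data.treatment[i][~np.isnan(data.treatment[i])]
            if xi.size < 2 or xpi.size < 2:
                continue
            p[i] = stats.mannwhitneyu(xpi, xi, alternative="greater").pvalue
    return PValueVector(p, test="wilcoxon")


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

@dataclass
class ModeratedTFit:
    """Empirical-Bayes variance shrinkage fit and moderated t-statistics."""

    dhat: np.ndarray
    s2: np.ndarray
    df: np.ndarray
    v_unscaled: np.ndarray  # unscaled variance of dhat (1/n or 1/n + 1/n')
    d0: float               # prior df (may be +inf)
    s02: float              # prior variance scale
    s2_post: np.ndarray
    tstat: np.ndarray
    df_total: np.ndarray
    pvalues: np.ndarray


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton's method (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-8:
            break
    return y


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match ``log s^2`` to a scaled F, returning ``(d0, s0^2)``."""
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive variance")
    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, dfo / 2.0))
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond sampling noise: variances effectively equal
        d0 = np.inf
        s02 = float(np.mean(s2[ok]))
    return d0, s02


def fit_moderated_t(data: GroupedExpression, d0: float | None = None,
                    s02: float | None = None) -> ModeratedTFit:
    """Fit the hierarchical variance model and compute moderated t-statistics.

    ``d0``/``s02`` may be supplied to bypass the hyperparameter fit (the
    ``d0 -> 0`` limit recovers the classical t exactly).
    """
    dhat = estimate_dhat(data).dhat
    if data.paired:
        _, s2, n_i = _paired_stats(data)
        df = np.where(n_i >= 2, n_i - 1.0, np.nan)
        v = 1.0 / n_i
    else:
        _, ssx, n = _group_stats(data.control)
        _, ssxp, nprime = _group_stats(data.treatment)
        ok = (n >= 2) & (nprime >= 2)
        df = np.where(ok, n + nprime - 2.0, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = (ssx + ssxp) / df
            v = 1.0 / n + 1.0 / nprime
    if d0 is None or s02 is None:
        d0_fit, s02_fit = fit_f_dist(s2, df)
        d0 = d0_fit if d0 is None else d0
        s02 = s02_fit if s02 is None else s02
    with np.errstate(invalid="ignore"):
        if np.isinf(d0):
            s2_post = np.where(np.isfinite(df), s02, np.nan)
        else:
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0
        tstat = dhat / np.sqrt(s2_post * v)
        p = stats.t.sf(tstat, np.minimum(df_total, 1e300))
    return ModeratedTFit(dhat, s2, df, np.broadcast_to(np.asarray(v, float), dhat.shape).copy(),
                         float(d0), float(s02), s2_post, tstat, df_total, p)


def estimate_effect_prior_var(fit: ModeratedTFit, proportion: float = 0.01,
                              v0_lim: tuple[float, float] | None = None) -> float:
    """Estimate the unscaled prior variance ``v0`` of the effect under H'.

    Follows the standard moderated-t convention: the top ``proportion`` of
    |t| values are assumed differentially expressed; each target |t| is
    compared with the corresponding tail quantile of the null t to back
    out the variance inflation, and the results are averaged.  ``v0`` is
    in units of the gene variance, so the default clamp is the squared
    coefficient-SD window (0.1, 4)^2 divided by the prior scale ``s0^2``.
    """
    if v0_lim is None:
        v0_lim = (0.01 / fit.s02, 16.0 / fit.s02)
    ok = np.isfinite(fit.tstat)
    t = np.abs(fit.tstat[ok])
    v1 = fit.v_unscaled[ok]
    dfc = np.minimum(fit.df_total[ok], 1e300)
    ngenes = t.size
    ntarget = int(np.ceil(proportion / 2.0 * ngenes))
    if ntarget < 1:
        return v0_lim[0] if v0_lim else 0.0
    p_assumed = max(ntarget / ngenes, proportion)
    order = np.argsort(t)[::-1][:ntarget]
    tt, v1t, dft = t[order], v1[order], dfc[order]
    r = stats.rankdata(tt)
    p0 = 2.0 * stats.t.sf(tt, dft)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p_assumed) * p0) / p_assumed
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, dft[pos])
        v0[pos] = v1t[pos] * ((tt[pos] / qtarget) ** 2 - 1.0)
    if v0_lim is not None:
        v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(v0.mean())


def log_odds_de(fit: ModeratedTFit, pi0: float, v0: float) -> np.ndarray:
    """Log posterior odds of differential expression given ``pi(H0)``.

    ``omega_i = (1-pi0)/pi0 * sqrt(v/(v+v0)) *
    [(t^2 + d) / (t^2 v/(v+v0) + d)]^((d+1)/2)`` with ``d`` the total
    (prior + residual) degrees of freedom.
    """
    t2 = fit.tstat**2
    d = np.minimum(fit.df_total, 1e300)
    r = fit.v_unscaled / (fit.v_unscaled + v0)
    with np.errstate(invalid="ignore", divide="ignore"):
        kernel = (d + 1.0) / 2.0 * (np.log(t2 + d) - np.log(r * t2 + d))
        return np.log((1.0 - pi0) / pi0) + 0.5 * np.log(r) + kernel


@dataclass
class LogOddsState:
    pi0: float
    trajectory: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    v0: float = 0.0


def iterate_pi0(fit: ModeratedTFit, start: float = 0.9, tol: float = 1e-3,
                max_iter: int = 100, v0: float | None = None,
                proportion: float = 0.01) -> LogOddsState:
    """Fixed-point iteration for the null proportion ``pi(H0)``.

    The update is the mean posterior null probability
    ``pi_k = mean_i (1 + omega_i(pi_{k-1}))^{-1}``; iteration stops when
    the absolute update is below ``tol`` or its sign flips.
    """
    if v0 is None:
        v0 = estimate_effect_prior_var(fit, proportion)
    traj = [start]
    prev_diff = None
    for k in range(1, max_iter + 1):
        lo = log_odds_de(fit, traj[-1], v0)
        post_null = 1.0 / (1.0 + np.exp(lo[np.isfinite(lo)]))
        new = float(post_null.mean())
        diff = new - traj[-1]
        traj.append(new)
        if abs(diff) < tol or diff == 0.0:
            return LogOddsState(new, traj, k, True, v0)
        if prev_diff is not None and diff * prev_diff < 0:
            return LogOddsState(new, traj, k, True, v0)
        prev_diff = diff
    raise RuntimeError(f"pi(H0) iteration failed to converge; trajectory={traj}")


def limma_prob(fit: ModeratedTFit, state: LogOddsState) -> np.ndarray:
    """Equivalence probability ``(1 + omega_i(pi(H0)))^{-1}`` (local FDR form)."""
    lo = log_odds_de(fit, state.pi0, state.v0)
    with np.errstate(over="ignore", invalid="ignore"):
        pi = np.where(lo >= 0, np.exp(-lo) / (1 + np.exp(-lo)), 1.0 / (1.0 + np.exp(lo)))
    return np.where(np.isfinite(lo), pi, np.nan)


# ---------------------------------------------------------------------------
# Local FDR
# ---------------------------------------------------------------------------

@dataclass
class LocalFdrFit:
    z: np.ndarray
    fdr: np.ndarray
    null_kind: str
    pi0: float
    null_center: float
    null_scale: float
    bin_mids: np.ndarray
    f_bins: np.ndarray  # fitted marginal density at bin midpoints


def _fit_marginal_density(z: np.ndarray, bins: int, spline_df: int):
    lo, hi = z.min(), z.max()
    span = max(hi - lo, 1e-6)
    lo -= 0.01 * span
    hi += 0.01 * span
    edges = np.linspace(lo, hi, bins + 1)
    width = edges[1] - edges[0]
    counts, _ = np.histogram(z, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    design = patsy.dmatrix("cr(x, df=%d)" % spline_df, {"x": mids}, return_type="dataframe")
    model = sm.GLM(counts, np.asarray(design), family=sm.families.Poisson())
    res = model.fit()
    mu = np.maximum(res.fittedvalues, 1e-12)
    f = mu / (z.size * width)
    return mids, f


def local_fdr(p: PValueVector, null_kind: str = "theoretical", bins: int = 120,
              spline_df: int = 7, central_frac: float = 0.5,
              min_genes: int = 200) -> LocalFdrFit:
    """Map one-sided p-values to local false discovery rates.

    ``z = Phi^{-1}(1 - p)`` (p clipped away from {0, 1}); the marginal
    density is fit by Poisson spline regression on ``bins`` histogram
    bins; the null is either the standard normal (``theoretical``) with
    ``pi0`` estimated from the central peak, or a normal with center,
    spread and proportion fitted by maximum likelihood on the central
    ``central_frac`` quantile interval of z (``empirical``; the default
    excludes a quarter of the genes on each flank).
    """
    if null_kind not in {"theoretical", "empirical"}:
        raise ValueError(f"unknown null_kind {null_kind!r}")
    pv = np.asarray(p.p, dtype=float)
    usable = np.isfinite(pv)
    if usable.sum() < min_genes:
        raise ValueError(
            f"local FDR needs >= {min_genes} genes with defined p-values "
            f"(got {int(usable.sum())})"
        )
    z = np.full(pv.shape, np.nan)
    z[usable] = stats.norm.ppf(1.0 - np.clip(pv[usable], _P_CLIP, 1.0 - _P_CLIP))
    zu = z[usable]

    mids, f_bins = _fit_marginal_density(zu, bins, spline_df)

    qlo, qhi = np.quantile(zu, [0.5 - central_frac / 2, 0.5 + central_frac / 2])
    central = (mids >= qlo) & (mids <= qhi)
    if central.sum() < 3:
        central = np.argsort(np.abs(mids - np.median(zu)))[:5]

    if null_kind == "theoretical":
        center, scale = 0.0, 1.0
        ratio = f_bins[central] / stats.norm.pdf(mids[central])
        pi0 = float(min(1.0, ratio.min()))
    else:
        center, scale, pi0 = _empirical_null_mle(zu, qlo, qhi)

    f0 = stats.norm.pdf(z, loc=center, scale=scale)
    log_f = np.interp(z, mids, np.log(f_bins))
    with np.errstate(invalid="ignore"):
        fdr = np.clip(pi0 * f0 / np.exp(log_f), 0.0, 1.0)
    fdr[~usable] = np.nan
    return LocalFdrFit(z, fdr, null_kind, pi0, center, scale, mids, f_bins)


def _empirical_null_mle(z: np.ndarray, a: float, b: float):
    """Truncated-normal ML fit of (center, scale, proportion) on ``[a, b]``."""
    inside = z[(z >= a) & (z <= b)]
    n0, n = inside.size, z.size
    if n0 < 10:
        raise ValueError("too few central z-values for empirical null fit")

    def negloglik(theta):
        delta, log_sigma = theta
        sigma = np.exp(log_sigma)
        h = stats.norm.cdf((b - delta) / sigma) - stats.norm.cdf((a - delta) / sigma)
        if h <= 0:
            return np.inf
        ll_trunc = np.sum(stats.norm.logpdf(inside, delta, sigma)) - n0 * np.log(h)
        p0 = min(1.0, n0 / (n * h))
        q = p0 * h
        ll_binom = n0 * np.log(q) + (n - n0) * np.log1p(-q) if q < 1 else 0.0
        return -(ll_trunc + ll_binom)

    from scipy.optimize import minimize

    start = np.array([np.median(inside), np.log(max(np.std(inside), 0.05))])
    res = minimize(negloglik, start, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 500})
    delta, sigma = res.x[0], float(np.exp(res.x[1]))
    h = stats.norm.cdf((b - delta) / sigma) - stats.norm.cdf((a - delta) / sigma)
    pi0 = float(min(1.0, n0 / (n * h)))
    return float(delta), sigma, pi0


# ---------------------------------------------------------------------------
# Composed selectors
# ---------------------------------------------------------------------------

def eb_selector(data: GroupedExpression, variant: str, **kwargs) -> np.ndarray:
    """Dispatch the six hierarchical selector variants by label."""
    if variant == "t_locfdr":
        return local_fdr(t_pvalues(data), "theoretical", **kwargs).fdr
    if variant == "wilcoxon_locfdr":
        return local_fdr(wilcoxon_pvalues(data), "theoretical", **kwargs).fdr
    if variant == "modt_locfdr":
        return local_fdr(PValueVector(fit_moderated_t(data).pvalues, test="moderated_t"),
                         "theoretical", **kwargs).fdr
    if variant == "t_empnull":
        return local_fdr(t_pvalues(data), "empirical", **kwargs).fdr
    if variant == "wilcoxon_empnull":
        return local_fdr(wilcoxon_pvalues(data), "empirical", **kwargs).fdr
    if variant == "modt_limma":
        fit = fit_moderated_t(data)
        state = iterate_pi0(fit)
        return limma_prob(fit, state)
    raise ValueError(f"unknown empirical-Bayes variant {variant!r}")
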