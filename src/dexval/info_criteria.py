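"""Per-gene model-selection selectors: Bayes factor, BIC, and AICc.

Each gene is treated in isolation under two normal-error linear models:

* ``H``  (equivalent expression): zero mean log-ratio (paired) or a single
  common mean for both groups (unpaired, equal within-group variance);
* ``H'`` (differential expression): a free mean log-ratio, or two distinct
  group means.

Both models are summarised by residual sums of squares.  With ``d_j`` the
complete paired log-ratios, ``SSR_H = sum d_j^2`` and
``SSR_H' = sum (d_j - dbar)^2``; unpaired, ``SSR_H`` is the residual SS
about the pooled mean of all ``N = n + n'`` values and ``SSR_H'`` the
within-group residual SS.  Parameter counts are (1, 2) paired and (2, 3)
unpaired (each model also fits a variance).

The Bayes factor puts equal prior mass 1/2 on each hypothesis, a Jeffreys
``sigma^-2`` prior on the variance, and a unit-information Zellner g-prior
on the mean(-difference) parameter under ``H'`` (g equal to the effective
sample size).  Integrating both models analytically gives

    BF(H : H') = sqrt(1 + g) * (Q / SSR_H)^(Neff / 2),
    Q = SSR_H' + (SSR_H - SSR_H') / (1 + g),

with ``Neff = n, g = n`` paired and ``Neff = N - 1, g = N`` unpaired (one
degree of freedom is absorbed by the flat common-mean integral).  The
posterior probability of equivalent expression is ``BF / (1 + BF)``.  The
formula depends on the data only through the SSR ratio, so it is invariant
to rescaling the expression values.

BIC and AICc are evaluated with the maximum-likelihood variance
``SSR / N`` inside the log; additive constants cancel in the pairwise
differences that feed the model weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import GroupedExpression

__all__ = [
    "SSRTable",
    "SSRPair",
    "compute_ssr_table",
    "compute_ssr",
    "bayes_factor_prob",
    "bic_prob",
    "aicc_prob",
]


@dataclass
class SSRPair:
    """Residual sums of squares for one gene under the null/alternative."""

    ssr_null: float
    ssr_alt: float
    N: int
    k_null: int
    k_alt: int


@dataclass
class SSRTable:
    """Vectorised per-gene SSR summaries (NaN where a gene is undefined)."""

    ssr_null: np.ndarray
    ssr_alt: np.ndarray
    N: np.ndarray          # usable sample count per gene
    n: np.ndarray          # usable control count (equals N for paired)
    n_prime: np.ndarray
    k_null: int
    k_alt: int
    paired: bool


def compute_ssr_table(data: GroupedExpression) -> SSRTable:
    """Complete-case per-gene SSRs under both hypotheses."""
    if data.paired:
        d = data.differences()
        valid = ~np.isnan(d)
        n_i = valid.sum(axis=1)
        ok = n_i >= 2
        dbar = np.where(
            ok, np.nansum(np.where(valid, d, 0.0), axis=1) / np.maximum(n_i, 1), np.nan
        )
        ssr_null = np.where(ok, np.nansum(np.where(valid, d, 0.0) ** 2, axis=1), np.nan)
        resid = np.where(valid, d - dbar[:, None], 0.0)
        ssr_alt = np.where(ok, np.sum(resid**2, axis=1), np.nan)
        return SSRTable(ssr_null, ssr_alt, n_i.astype(float), n_i.astype(float),
                        n_i.astype(float), 1, 2, True)

    x, xp = data.control, data.treatment
    vx, vxp = ~np.isnan(x), ~np.isnan(xp)
    n_i, np_i = vx.sum(axis=1), vxp.sum(axis=1)
    ok = (n_i >= 2) & (np_i >= 2)
    sx = np.nansum(np.where(vx, x, 0.0), axis=1)
    sxp = np.nansum(np.where(vxp, xp, 0.0), axis=1)
    xbar = sx / np.maximum(n_i, 1)
    xpbar = sxp / np.maximum(np_i, 1)
    pooled = (sx + sxp) / np.maximum(n_i + np_i, 1)
    ssr_alt = np.sum(np.where(vx, x - xbar[:, None], 0.0) ** 2, axis=1) + np.sum(
        np.where(vxp, xp - xpbar[:, None], 0.0) ** 2, axis=1
    )
    ssr_null = np.sum(np.where(vx, x - pooled[:, None], 0.0) ** 2, axis=1) + np.sum(
        np.where(vxp, xp - pooled[:, None], 0.0) ** 2, axis=1
    )
    ssr_null = np.where(ok, ssr_null, np.nan)
    ssr_alt = np.where(ok, ssr_alt, np.nan)
    return SSRTable(ssr_null, ssr_alt, (n_i + np_i).astype(float),
                    n_i.astype(float), np_i.astype(float), 2, 3, False)


def compute_ssr(data: GroupedExpression, gene: int) -> SSRPair:
    """SSRs for a single gene; raises if replication is insufficient."""
    t = compute_ssr_table(data)
    if not np.isfinite(t.ssr_null[gene]):
        raise ValueError(f"gene {data.gene_ids[gene]!r}: insufficient replication")
    return SSRPair(float(t.ssr_null[gene]), float(t.ssr_alt[gene]),
                   int(t.N[gene]), t.k_null, t.k_alt)


def _odds_to_pi(log_odds_eq: np.ndarray) -> np.ndarray:
    """pi = omega/(1+omega) computed stably from log odds of equivalence."""
    with np.errstate(over="ignore"):
        return np.where(
            log_odds_eq >= 0,
            1.0 / (1.0 + np.exp(-log_odds_eq)),
            np.exp(log_odds_eq) / (1.0 + np.exp(log_odds_eq)),
        )


def bayes_factor_log(t: SSRTable) -> np.ndarray:
    """log BF(H : H') under the unit-information g-prior (vectorised)."""
    if t.paired:
        g = t.N
        neff = t.N
    else:
        g = t.N
        neff = t.N - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        q = t.ssr_alt + (t.ssr_null - t.ssr_alt) / (1.0 + g)
        return 0.5 * np.log1p(g) + 0.5 * neff * (np.log(q) - np.log(t.ssr_null))


def bayes_factor_prob(data: GroupedExpression) -> np.ndarray:
    """Posterior probability of equivalent expression from the Bayes factor."""
    t = compute_ssr_table(data)
    log_bf = bayes_factor_log(t)
    bad = np.isfinite(t.ssr_null) & (t.ssr_null <= 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} gene(s) with zero total SSR masked")
    return np.where(np.isfinite(log_bf), _odds_to_pi(log_bf), np.nan)


def _bic(ssr: np.ndarray, N: np.ndarray, k: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return N * np.log(ssr / N) + k * np.log(N)


def bic_prob(data: GroupedExpression) -> np.ndarray:
    """Equivalence probability from BIC model weights (equal prior mass)."""
    t = compute_ssr_table(data)
    bic_null = _bic(t.ssr_null, t.N, t.k_null)
    bic_alt = _bic(t.ssr_alt, t.N, t.k_alt)
    defined = np.isfinite(t.ssr_null)
    # SSR = 0 drives BIC to -inf under that hypothesis: probability saturates.
    null_zero = defined & (t.ssr_null <= 0)
    alt_zero = defined & (t.ssr_alt <= 0) & ~null_zero
    if null_zero.any() or alt_zero.any():
        warnings.warn(
            f"{int(null_zero.sum() + alt_zero.sum())} gene(s) with zero SSR: "
            "BIC probability saturated"
        )
    with np.errstate(invalid="ignore"):
        pi = _odds_to_pi(-(bic_null - bic_alt) / 2.0)
    pi = np.where(alt_zero, 0.0, pi)
    pi = np.where(null_zero, 1.0, pi)  # both zero => perfect fit either way
    return np.where(defined, pi, np.nan)


def aicc_prob(data: GroupedExpression) -> np.ndarray:
    """Equivalence probability from the Akaike-weight ratio of AICc values."""
    t = compute_ssr_table(data)
    denom_ok = t.N - t.k_alt - 1 >= 1
    if not np.any(denom_ok & np.isfinite(t.ssr_null)):
        raise ValueError(
            "AICc undefined: N - k - 1 < 1 for every gene "
            f"(paired designs need n >= {t.k_alt + 2})"
        )

    def aicc(ssr, N, k):
        with np.errstate(divide="ignore", invalid="ignore"):
            return N * np.log(ssr / N) + 2 * k + 2 * k * (k + 1) / (N - k - 1)

    a_null = aicc(t.ssr_null, t.N, t.k_null)
    a_alt = aicc(t.ssr_alt, t.N, t.k_alt)
    defined = np.isfinite(t.ssr_null) & denom_ok
    dropped = np.isfinite(t.ssr_null) & ~denom_ok
    if dropped.any():
        warnings.warn(f"{int(dropped.sum())} gene(s) below the AICc sample bound masked")
    null_zero = defined & (t.ssr_null <= 0)
    alt_zero = defined & (t.ssr_alt <= 0) & ~null_zero
    with np.errstate(invalid="ignore"):
        pi = _odds_to_pi(-(a_null - a_alt) / 2.0)
    pi = np.where(alt_zero, 0.0, pi)
    pi = np.where(null_zero, 1.0, pi)
    return np.where(defined, pi, np.nan)
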