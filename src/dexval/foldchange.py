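"""Fold-change selectors and the two trivial reference selectors.

The hard rule calls gene ``i`` differentially expressed (``pi = 0``) when
its estimated fold change ``exp(|dhat_i|)`` is at least the threshold
``phi``; down-regulation is treated symmetrically with up-regulation.

The smooth ("shrinkage") rule replaces the step by
``pi(dhat) = min(1, exp(-(dhat + 1)))``, a smooth decreasing function of
the signed fold-change scale ``exp(dhat)`` (equivalently
``pi = 1 / (e * exp(dhat))`` capped at one).  ``1 - pi`` acts as the
shrinkage weight applied to ``dhat`` when forming predictions, so strong
up-regulation keeps nearly the full estimate while weak or negative
estimates are shrunk hard toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GroupedExpression

__all__ = [
    "FoldChangeEstimate",
    "estimate_dhat",
    "fc_hard",
    "fc_shrinkage",
    "trivial_selector",
]


@dataclass
class FoldChangeEstimate:
    """Per-gene estimated mean log-difference ``dhat_i`` (NaN where undefined)."""

    dhat: np.ndarray


def _nanmean_rows(a: np.ndarray) -> np.ndarray:
    out = np.full(a.shape[0], np.nan)
    counts = np.sum(~np.isnan(a), axis=1)
    ok = counts > 0
    with np.errstate(invalid="ignore"):
        out[ok] = np.nanmean(a[ok], axis=1)
    return out


def estimate_dhat(data: GroupedExpression) -> FoldChangeEstimate:
    """``dhat_i``: mean paired log-ratio, or difference of group means."""
    if data.paired:
        return FoldChangeEstimate(_nanmean_rows(data.differences()))
    return FoldChangeEstimate(
        _nanmean_rows(data.treatment) - _nanmean_rows(data.control)
    )


def fc_hard(dhat: FoldChangeEstimate, phi: float) -> np.ndarray:
    """Hard threshold: ``pi = 0`` iff ``exp(|dhat|) >= phi`` (boundary differential)."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    d = dhat.dhat
    pi = np.where(np.exp(np.abs(d)) >= phi, 0.0, 1.0)
    return np.where(np.isnan(d), np.nan, pi)


def fc_shrinkage(dhat: FoldChangeEstimate) -> np.ndarray:
    """Smooth fold-change rule: ``pi = min(1, exp(-(dhat + 1)))``."""
    d = dhat.dhat
    with np.errstate(over="ignore"):
        pi = np.clip(np.exp(-(d + 1.0)), 0.0, 1.0)
    return np.where(np.isnan(d), np.nan, pi)


def trivial_selector(data: GroupedExpression, which: str) -> np.ndarray:
    """Data-ignoring references: every null true (``pi = 1``) or false (``pi = 0``)."""
    if which == "all_nulls_true":
        return np.ones(data.m)
    if which == "all_nulls_false":
        return np.zeros(data.m)
    raise ValueError(f"unknown trivial selector {which!r}")
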