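"""Leave-one-out cross-validated squared prediction error.

A selector's best prediction of the next log-difference for gene ``i`` is
the posterior expected degree of expression
``(1 - pi_i) * dhat_i`` -- the maximum-likelihood estimate weighted by the
probability of differential expression.  Leave-one-out cross validation
scores this prediction against held-out replicates:

* paired: fold ``j`` removes replicate pair ``j``; the selector is re-fit
  on the reduced data (including any cross-gene fits, so there is no
  leakage), and the held-out log-ratio ``d_{i,j}`` is predicted from the
  leave-one-out mean ``dhat_{i,(-j)}``;
* unpaired: all ``n * n'`` folds removing one control and one treatment
  column; the held-out quantity is ``x'_{i,j'} - x_{i,j}``.

Summaries: the total-error ratio against a base selector (the default
report), plus the mean and half-sample mode of the per-gene error ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import EquivalenceProbabilities, GroupedExpression, SelectorAlgorithm
from .foldchange import FoldChangeEstimate, estimate_dhat

__all__ = [
    "GeneErrorTable",
    "ErrorSummary",
    "predict_degree",
    "loocv",
    "loocv_paired",
    "loocv_unpaired",
    "half_sample_mode",
    "summarize_errors",
]


@dataclass
class GeneErrorTable:
    """Per-gene mean squared prediction errors for one selector."""

    errors: np.ndarray       # NaN where no fold was defined
    fold_counts: np.ndarray  # number of folds contributing per gene
    algorithm_label: str


@dataclass
class ErrorSummary:
    algorithm_label: str
    base_label: str
    absolute_ratio: float    # sum of errors / sum of base errors
    relative_mean: float     # mean of per-gene error ratios
    relative_mode: float     # half-sample mode of the same ratios
    n_genes: int
    n_excluded: int          # genes dropped from ratio summaries (base error 0 or NaN)


def predict_degree(pi: EquivalenceProbabilities | np.ndarray,
                   dhat: FoldChangeEstimate | np.ndarray) -> np.ndarray:
    """Posterior expected degree of expression ``(1 - pi) * dhat``."""
    p = pi.pi if isinstance(pi, EquivalenceProbabilities) else np.asarray(pi, float)
    d = dhat.dhat if isinstance(dhat, FoldChangeEstimate) else np.asarray(dhat, float)
    return (1.0 - p) * d


def loocv_paired(data: GroupedExpression, algorithm: SelectorAlgorithm) -> GeneErrorTable:
    """Paired leave-one-out CV: one fold per replicate pair."""
    if not data.paired:
        raise ValueError("loocv_paired requires paired data")
    if data.n < 3:
        raise ValueError("paired LOOCV needs n >= 3 so each fold keeps >= 2 pairs")
    d = data.differences()
    sq_sum = np.zeros(data.m)
    counts = np.zeros(data.m)
    for j in range(data.n):
        sub = data.drop_pair(j)
        pi_fold = algorithm.evaluate(sub).pi
        pred = predict_degree(pi_fold, estimate_dhat(sub))
        term = (d[:, j] - pred) ** 2
        ok = np.isfinite(term)
        sq_sum[ok] += term[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        errors = np.where(counts > 0, sq_sum / np.maximum(counts, 1), np.nan)
    return GeneErrorTable(errors, counts, algorithm.label)


def loocv_unpaired(data: GroupedExpression, algorithm: SelectorAlgorithm) -> GeneErrorTable:
    """Unpaired leave-one-out CV over all ``n * n'`` column-pair folds."""
    if data.paired:
        raise ValueError("loocv_unpaired requires unpaired data")
    if data.n < 3 or data.n_prime < 3:
        raise ValueError("unpaired LOOCV needs n >= 3 and n' >= 3")
    sq_sum = np.zeros(data.m)
    counts = np.zeros(data.m)
    for j in range(data.n):
        for jp in range(data.n_prime):
            sub = data.drop_columns(j, jp)
            pi_fold = algorithm.evaluate(sub).pi
            pred = predict_degree(pi_fold, estimate_dhat(sub))
            term = (data.treatment[:, jp] - data.control[:, j] - pred) ** 2
            ok = np.isfinite(term)
            sq_sum[ok] += term[ok]
            counts[ok] += 1
    with np.errstate(invalid="ignore"):
        errors = np.where(counts > 0, sq_sum / np.maximum(counts, 1), np.nan)
    return GeneErrorTable(errors, counts, algorithm.label)


def loocv(data: GroupedExpression, algorithm: SelectorAlgorithm) -> GeneErrorTable:
    """Dispatch to the paired or unpaired LOOCV engine."""
    return loocv_paired(data, algorithm) if data.paired else loocv_unpaired(data, algorithm)


def half_sample_mode(values) -> float:
    """Robust mode: recursively keep the shortest half of the sorted sample.

    Window length is ``ceil(k / 2)``; ties between equally short windows
    take the leftmost; once at most 3 points remain their mean is
    returned.
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("half_sample_mode of empty input")
    while x.size > 3:
        h = int(np.ceil(x.size / 2))
        widths = x[h - 1:] - x[: x.size - h + 1]
        j = int(np.argmin(widths))  # argmin takes the leftmost tie
        x = x[j: j + h]
    return float(x.mean())


def summarize_errors(errors: GeneErrorTable, base: GeneErrorTable) -> ErrorSummary:
    """Total-error ratio plus mean / half-sample-mode of per-gene ratios."""
    e, b = errors.errors, base.errors
    if e.shape != b.shape:
        raise ValueError("error tables cover different gene sets")
    both = np.isfinite(e) & np.isfinite(b)
    ratio_ok = both & (b > 0)
    excluded = int(both.sum() - ratio_ok.sum() + (~both).sum())
    if excluded:
        warnings.warn(
            f"{excluded} gene(s) excluded from ratio summaries "
            "(undefined or zero base error)"
        )
    ratios = e[ratio_ok] / b[ratio_ok]
    abs_ratio = float(e[both].sum() / b[both].sum()) if both.any() else np.nan
    return ErrorSummary(
        errors.algorithm_label,
        base.algorithm_label,
        abs_ratio,
        float(ratios.mean()) if ratios.size else np.nan,
        half_sample_mode(ratios) if ratios.size else np.nan,
        int(both.sum()),
        excluded,
    )
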