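"""Selector registry: label -> SelectorAlgorithm.

Labels mirror the figure legends of the assessment study:
fold-change rules (``fc_gt_1``, ``fc_gt_1.41``, ``fc_gt_2``,
``fc_shrinkage``), trivial references (``all_nulls_true``,
``all_nulls_false``), per-gene model-selection rules (``bayes_factor``,
``bic``, ``aicc``), and the hierarchical family (``t_locfdr``,
``wilcoxon_locfdr``, ``modt_locfdr``, ``t_empnull``, ``wilcoxon_empnull``,
``modt_limma``).
"""

from __future__ import annotations

from functools import partial

from .datamodel import SelectorAlgorithm
from . import empirical_bayes as eb
from . import foldchange as fc
from . import info_criteria as ic

__all__ = ["get_selector", "list_selectors", "HARD_THRESHOLD_LABELS",
           "HIERARCHICAL_LABELS"]

HARD_THRESHOLD_LABELS = ("fc_gt_1", "fc_gt_1.41", "fc_gt_2", "fc_gt_4")
HIERARCHICAL_LABELS = eb.EB_VARIANTS


def _fc_hard_fn(phi):
    return lambda data: fc.fc_hard(fc.estimate_dhat(data), phi)


_REGISTRY = {
    "fc_gt_1": SelectorAlgorithm("fc_gt_1", _fc_hard_fn(1.0)),
    "fc_gt_1.41": SelectorAlgorithm("fc_gt_1.41", _fc_hard_fn(2.0**0.5)),
    "fc_gt_2": SelectorAlgorithm("fc_gt_2", _fc_hard_fn(2.0)),
    "fc_gt_4": SelectorAlgorithm("fc_gt_4", _fc_hard_fn(4.0)),
    "fc_shrinkage": SelectorAlgorithm(
        "fc_shrinkage", lambda data: fc.fc_shrinkage(fc.estimate_dhat(data))
    ),
    "all_nulls_true": SelectorAlgorithm(
        "all_nulls_true", partial(fc.trivial_selector, which="all_nulls_true")
    ),
    "all_nulls_false": SelectorAlgorithm(
        "all_nulls_false", partial(fc.trivial_selector, which="all_nulls_false")
    ),
    "bayes_factor": SelectorAlgorithm("bayes_factor", ic.bayes_factor_prob),
    "bic": SelectorAlgorithm("bic", ic.bic_prob),
    "aicc": SelectorAlgorithm("aicc", ic.aicc_prob),
}
for _v in eb.EB_VARIANTS:
    _REGISTRY[_v] = SelectorAlgorithm(_v, partial(eb.eb_selector, variant=_v),
                                      needs_all_genes=True)


def get_selector(label: str) -> SelectorAlgorithm:
    try:
        return _REGISTRY[label]
    except KeyError:
        raise ValueError(f"unknown selector {label!r}; choose from {sorted(_REGISTRY)}")


def list_selectors() -> list[str]:
    return sorted(_REGISTRY)
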