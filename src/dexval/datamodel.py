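"""Core data containers, TSV I/O, and the selector contract.

Expression data are held on the natural-log scale throughout: a
:class:`GroupedExpression` stores an ``m x n`` control matrix and an
``m x n'`` treatment matrix of log intensities (or log ratios), with
``NaN`` marking missing cells.  For paired designs column ``j`` of the
treatment matrix is hybridised/matched with column ``j`` of the control
matrix, so ``treatment - control`` is the matrix of per-replicate
log-ratios ``d_{i,j}``.

A gene selection algorithm ("selector") maps a :class:`GroupedExpression`
to a vector of per-gene probabilities of *equivalent* expression,
``pi[i] = P(H_i | data)``; ``1 - pi[i]`` is the probability of
differential expression.  Hard-threshold rules emit only 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupedExpression",
    "EquivalenceProbabilities",
    "SelectorAlgorithm",
    "DesignError",
    "load_expression_table",
    "paired_differences",
    "write_results_table",
]

_LOG_BASE_FACTORS = {"e": 1.0, "2": float(np.log(2.0)), "10": float(np.log(10.0))}


class DesignError(ValueError):
    """Raised when a design declaration contradicts the data layout."""


@dataclass
class GroupedExpression:
    """Two-group (optionally paired) log-scale expression matrices.

    Parameters
    ----------
    gene_ids
        Length-``m`` unique identifiers; order is preserved end-to-end.
    control, treatment
        ``m x n`` and ``m x n'`` float arrays on the natural-log scale.
        ``NaN`` entries are treated as masked (missing) cells.
    paired
        If true, ``n == n'`` and treatment column ``j`` pairs with
        control column ``j``.
    """

    gene_ids: list
    control: np.ndarray
    treatment: np.ndarray
    paired: bool

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=float)
        if self.control.ndim != 2 or self.treatment.ndim != 2:
            raise ValueError("expression matrices must be 2-D")
        m = len(self.gene_ids)
        if m < 1:
            raise ValueError("need at least one gene")
        if self.control.shape[0] != m or self.treatment.shape[0] != m:
            raise ValueError("matrix row counts must equal len(gene_ids)")
        if self.control.shape[1] < 2 or self.treatment.shape[1] < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.paired and self.control.shape[1] != self.treatment.shape[1]:
            raise DesignError("paired design requires n == n'")
        if len(set(map(str, self.gene_ids))) != m:
            raise ValueError("duplicate gene identifiers")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.control).any() or np.isinf(self.treatment).any():
                raise ValueError("unmasked entries must be finite (use NaN to mask)")

    # -- basic dimensions -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return self.control.shape[1]

    @property
    def n_prime(self) -> int:
        return self.treatment.shape[1]

    # -- derived views ----------------------------------------------------
    def differences(self) -> np.ndarray:
        """Per-replicate log-ratios ``d_{i,j} = x'_{i,j} - x_{i,j}`` (paired only)."""
        return paired_differences(self)

    def subset(self, rows) -> "GroupedExpression":
        rows = np.asarray(rows)
        return GroupedExpression(
            [self.gene_ids[i] for i in np.atleast_1d(rows)],
            np.atleast_2d(self.control[rows]),
            np.atleast_2d(self.treatment[rows]),
            self.paired,
        )

    def drop_pair(self, j: int) -> "GroupedExpression":
        """Remove replicate pair ``j`` (paired designs; used by LOO folds)."""
        if not self.paired:
            raise DesignError("drop_pair requires a paired design")
        keep = [k for k in range(self.n) if k != j]
        return GroupedExpression(
            self.gene_ids, self.control[:, keep], self.treatment[:, keep], True
        )

    def drop_columns(self, control_j: int, treatment_j: int) -> "GroupedExpression":
        """Remove one control and one treatment column (unpaired LOO folds)."""
        if self.paired:
            raise DesignError("drop_columns is for unpaired designs; use drop_pair")
        keep_c = [k for k in range(self.n) if k != control_j]
        keep_t = [k for k in range(self.n_prime) if k != treatment_j]
        return GroupedExpression(
            self.gene_ids, self.control[:, keep_c], self.treatment[:, keep_t], False
        )


@dataclass
class EquivalenceProbabilities:
    """Per-gene probabilities of equivalent expression emitted by a selector."""

    pi: np.ndarray
    algorithm_label: str
    needs_all_genes: bool = False

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        ok = self.pi[np.isfinite(self.pi)]
        if ok.size and (ok.min() < -1e-12 or ok.max() > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        self.pi = np.clip(self.pi, 0.0, 1.0)


@dataclass
class SelectorAlgorithm:
    """A named, deterministic map ``GroupedExpression -> EquivalenceProbabilities``.

    ``needs_all_genes`` is true for selectors that pool information across
    genes (local-FDR and moderated-t families); for those, evaluating a
    single-gene slice is not equivalent to slicing the full-data result.
    """

    label: str
    fn: Callable[[GroupedExpression], np.ndarray]
    needs_all_genes: bool = False

    def evaluate(self, data: GroupedExpression) -> EquivalenceProbabilities:
        pi = np.asarray(self.fn(data), dtype=float)
        if pi.shape != (data.m,):
            raise ValueError(
                f"selector {self.label!r} returned shape {pi.shape}, expected ({data.m},)"
            )
        return EquivalenceProbabilities(pi, self.label, self.needs_all_genes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a gene_id column plus sample columns")
    gene_col = df.columns[0]
    ids = df[gene_col].tolist()
    if len(set(ids)) != len(ids):
        dups = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene id {dups!r} in {path}")
    df = df.set_index(gene_col)
    return df.apply(pd.to_numeric, errors="coerce")


def load_expression_table(
    path, design: Mapping, treatment_path=None
) -> GroupedExpression:
    """Read a gene x replicate TSV (or pair of TSVs) into a :class:`GroupedExpression`.

    ``design`` declares the layout:

    ``{"layout": "paired_ratio", "log_base": "2"}``
        one matrix of log-ratios, read as ``x' - x`` directly (control set
        to zero so that ``differences()`` returns the ratios);
    ``{"layout": "paired_two_channel"}``
        two matrices with matched columns (``treatment_path`` or
        ``treatment_columns``/``control_columns`` of one file);
    ``{"layout": "two_group", "control_columns": [...], "treatment_columns": [...]}``
        two independent groups from one file, or two files.

    ``log_base`` in ``{"2", "10", "e"}`` (default ``"e"``) declares the
    base of the input values; everything is rescaled to natural log.
    """
    layout = design.get("layout")
    if layout not in {"paired_ratio", "paired_two_channel", "two_group"}:
        raise DesignError(f"unknown layout {layout!r}")
    factor = _LOG_BASE_FACTORS.get(str(design.get("log_base", "e")))
    if factor is None:
        raise DesignError(f"unknown log_base {design.get('log_base')!r}")

    main = _read_matrix(path)
    if layout == "paired_ratio":
        vals = main.to_numpy(dtype=float) * factor
        return GroupedExpression(
            main.index.tolist(), np.zeros_like(vals), vals, paired=True
        )

    if treatment_path is not None:
        other = _read_matrix(treatment_path)
        if list(other.index) != list(main.index):
            raise ValueError("control and treatment files list different genes")
        control, treatment = main, other
    else:
        c_cols = design.get("control_columns")
        t_cols = design.get("treatment_columns")
        if not c_cols or not t_cols:
            raise DesignError(
                "single-file designs need control_columns and treatment_columns"
            )
        missing = [c for c in list(c_cols) + list(t_cols) if c not in main.columns]
        if missing:
            raise DesignError(f"design references absent columns: {missing}")
        control, treatment = main[list(c_cols)], main[list(t_cols)]

    paired = layout == "paired_two_channel"
    if paired and control.shape[1] != treatment.shape[1]:
        raise DesignError(
            f"paired design with unequal column counts "
            f"({control.shape[1]} vs {treatment.shape[1]})"
        )
    return GroupedExpression(
        main.index.tolist(),
        control.to_numpy(dtype=float) * factor,
        treatment.to_numpy(dtype=float) * factor,
        paired,
    )


def paired_differences(data: GroupedExpression) -> np.ndarray:
    """``d_{i,j} = x'_{i,j} - x_{i,j}``; NaN wherever either operand is masked."""
    if not data.paired:
        raise DesignError("paired_differences requires a paired design")
    return data.treatment - data.control


def write_results_table(records, path) -> None:
    """Write a rectangular result table as TSV with round-trippable floats."""
    df = pd.DataFrame(records)
    # repr() gives the shortest decimal string that round-trips exactly
    df.to_csv(path, sep="\t", index=False,
              float_format=lambda v: repr(float(v)))
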