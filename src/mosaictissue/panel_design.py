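"""Collect-and-filter gene-panel selection for targeted spatial assays.

A candidate pool assembled from prior knowledge, proteomic panel overlap and
data-driven statistics is filtered down to the experimental panel size using
three primitives:

* :func:`compute_variability` — fraction of cells with \\|z-scaled expression\\|
  above 1, a simple dispersion statistic on scaled data;
* :func:`cumulative_weight_select` — per cell-type class, keep the top-ranked
  classifier features whose cumulative relative weight stays below a budget;
* :func:`collect_and_filter` — the explicit two-clause inclusion formula
  combining expression level, variability, manual priority and category
  membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneCandidate",
    "WeightMatrix",
    "compute_variability",
    "cumulative_weight_select",
    "collect_and_filter",
]


@dataclass
class GeneCandidate:
    """One candidate gene with the statistics used by the inclusion formula.

    ``mean_expr`` is the mean normalized expression in the gene's highest
    expressing cell type (or in epithelial/malignant cells for genes chosen for
    disease relevance); ``variability`` and ``priority`` are in [0, 1];
    ``categories`` is the non-empty set of selection categories the gene
    belongs to (out of nine); ``selection_types`` the finer selection types.
    """

    gene: str
    categories: frozenset = field(default_factory=frozenset)
    selection_types: frozenset = field(default_factory=frozenset)
    priority: float = 0.0
    mean_expr: float = 0.0
    variability: float = 0.0

    def __post_init__(self) -> None:
        self.categories = frozenset(self.categories)
        self.selection_types = frozenset(self.selection_types)
        if not self.categories:
            raise ValueError(f"{self.gene}: categories must be non-empty")
        if not 0.0 <= self.priority <= 1.0:
            raise ValueError(f"{self.gene}: priority must be in [0, 1]")
        if not 0.0 <= self.variability <= 1.0:
            raise ValueError(f"{self.gene}: variability must be in [0, 1]")


@dataclass
class WeightMatrix:
    """Per-class nonnegative relative feature weights (each class sums to 1)."""

    weights: pd.DataFrame  # classes x genes

    @classmethod
    def from_raw(cls, raw: pd.DataFrame) -> "WeightMatrix":
        """Normalize absolute classifier weights: abs, then sum-to-1 per class."""
        w = raw.abs()
        sums = w.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError("every class must have at least one nonzero weight")
        return cls(weights=w.div(sums, axis=0))

    def __post_init__(self) -> None:
        if (self.weights.to_numpy() < 0).any():
            raise ValueError("relative weights must be nonnegative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each class's relative weights must sum to 1")


def compute_variability(scaled_expression: np.ndarray, cutoff: float = 1.0) -> float:
    """Fraction of cells with absolute z-scaled expression above ``cutoff``."""
    z = np.asarray(scaled_expression, dtype=float)
    if z.size == 0:
        raise ValueError("empty expression vector")
    return float((np.abs(z) > cutoff).mean())


def cumulative_weight_select(
    weights: WeightMatrix, threshold: float | dict = 0.4
) -> dict[str, list[str]]:
    """Select, per class, the top-weighted genes within a cumulative budget.

    Genes are ranked by descending relative weight (ties broken by gene id for
    determinism).  A gene is included iff the cumulative weight of all strictly
    higher-ranked genes is below the threshold, so the gene whose prefix
    crosses the budget is itself included.  ``threshold`` may be a single value
    in (0, 1] or a per-class mapping.

    Returns a per-class mapping of selected gene lists; the panel union with
    per-class provenance can be formed directly from it.
    """
    out: dict[str, list[str]] = {}
    for cls_name, row in weights.weights.iterrows():
        thr = threshold[cls_name] if isinstance(threshold, dict) else threshold
        if not 0 < thr <= 1:
            raise ValueError("threshold must be in (0, 1]")
        ranked = row[row > 0].sort_values(ascending=False, kind="mergesort")
        ranked = ranked.loc[
            sorted(ranked.index, key=lambda g: (-ranked[g], g))
        ]  # deterministic tie-break by gene id
        cum_before = np.concatenate([[0.0], np.cumsum(ranked.to_numpy())[:-1]])
        out[str(cls_name)] = [g for g, c in zip(ranked.index, cum_before) if c < thr]
    return out


def collect_and_filter(candidates: list[GeneCandidate]) -> pd.DataFrame:
    """Apply the two-clause inclusion formula to a candidate list.

    A gene is included iff::

        (mean_expr > 0.15  OR  variability > 0.025  OR  n_categories > 1)
        AND
        (1.5 < mean_expr < 4  OR  variability > 0.25  OR  priority == 1
         OR  n_categories > 1)

    Returns a table with one row per candidate, a boolean ``included`` column
    and a clause trace for audit.
    """
    rows = []
    for c in candidates:
        ncat = len(c.categories)
        clause1 = (c.mean_expr > 0.15) or (c.variability > 0.025) or (ncat > 1)
        clause2 = (
            (1.5 < c.mean_expr < 4)
            or (c.variability > 0.25)
            or (c.priority == 1)
            or (ncat > 1)
        )
        rows.append(
            {
                "gene": c.gene,
                "mean_expr": c.mean_expr,
                "variability": c.variability,
                "priority": c.priority,
                "n_categories": ncat,
                "clause1": clause1,
                "clause2": clause2,
                "included": clause1 and clause2,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
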