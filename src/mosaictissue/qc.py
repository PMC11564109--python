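"""Quality-control procedures for single-cell and spatial expression data.

Three procedures are implemented:

1. **Group-median threshold filtering** for sc/snRNA-seq: hard caps on
   mitochondrial fraction, detected genes and UMIs, then per filter-group
   (cell type x protocol x chemistry) low thresholds chosen by a fixed ladder
   from the group median.  Thresholds are strict (keep iff metric > threshold)
   and group medians are computed on cap-surviving members.
2. **Adaptive minimum-counts filtering** for bead-like data: the minimum-counts
   threshold is raised step-wise until at most 35% of retained observations
   have fewer than 100 total counts.
3. **Per-sample pass/fail gates**: mean counts per observation (beads >= 150,
   segmented molecule cells >= 50) and, when a reference pseudobulk is
   available, Pearson r >= 0.60 of log1p mean expression over shared features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "QCConfig",
    "FilterGroup",
    "group_median_filter",
    "adaptive_min_counts_filter",
    "sample_gates",
    "filter_features_min_cells",
]


@dataclass
class QCConfig:
    """Thresholds for all three QC procedures.

    The gene/UMI ladders are ``(median_cutoff, low_threshold)`` pairs scanned
    from the highest median downward; the last entry is the floor.
    """

    max_mito_frac: float = 0.50
    max_genes: int = 8_000
    max_umis: int = 20_000
    gene_ladder: tuple[tuple[float, int], ...] = ((1_300, 700), (600, 300), (0, 100))
    umi_ladder: tuple[tuple[float, int], ...] = ((1_800, 1_100), (900, 600), (0, 300))
    # spatial minimums
    molecule_min_counts: int = 20
    molecule_min_genes: int = 1
    bead_min_counts: int = 30
    bead_min_genes: int = 30
    min_cells_per_feature: int = 3
    # adaptive filter
    adaptive_step: int = 10
    low_quality_counts: int = 100
    max_low_quality_fraction: float = 0.35
    # sample gates
    bead_gate_mean_counts: float = 150.0
    molecule_gate_mean_counts: float = 50.0
    pseudobulk_gate_r: float = 0.60

    def __post_init__(self) -> None:
        for ladder in (self.gene_ladder, self.umi_ladder):
            cutoffs = [c for c, _ in ladder]
            if cutoffs != sorted(cutoffs, reverse=True) or cutoffs[-1] != 0:
                raise ValueError("ladder cutoffs must descend and end at 0")


@dataclass
class FilterGroup:
    """A filter group: key (cell type x protocol x chemistry) and members."""

    key: str
    members: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _ladder_threshold(median: float, ladder) -> int:
    for cutoff, threshold in ladder:
        if median > cutoff:
            return threshold
    return ladder[-1][1]


def group_median_filter(
    metrics: pd.DataFrame,
    groups: list[FilterGroup] | None = None,
    cfg: QCConfig | None = None,
) -> tuple[pd.Index, pd.DataFrame]:
    """Hard-cap then group-median threshold filtering of sc/sn cells.

    Parameters
    ----------
    metrics
        Per-cell table with columns ``n_genes``, ``n_umis``, ``mito_frac`` and,
        if ``groups`` is not given, a ``group`` column.
    groups
        Optional explicit filter groups (member positions into ``metrics``).
    cfg
        Thresholds; defaults reproduce the standard configuration.

    Returns
    -------
    retained
        Index of cells passing both hard caps and their group's low thresholds.
    thresholds
        One row per group: median genes/UMIs (computed after hard caps) and the
        chosen low thresholds, for audit.
    """
    cfg = cfg or QCConfig()
    required = {"n_genes", "n_umis", "mito_frac"}
    if missing := required - set(metrics.columns):
        raise ValueError(f"metrics missing columns {sorted(missing)}")
    if groups is None:
        if "group" not in metrics.columns:
            raise ValueError("either groups or a 'group' column is required")
        groups = [
            FilterGroup(key=str(key), members=np.flatnonzero(metrics["group"].to_numpy() == key))
            for key in pd.unique(metrics["group"])
        ]

    passes_caps = (
        (metrics["mito_frac"].to_numpy() < cfg.max_mito_frac)
        & (metrics["n_genes"].to_numpy() < cfg.max_genes)
        & (metrics["n_umis"].to_numpy() < cfg.max_umis)
    )

    retained_mask = np.zeros(len(metrics), dtype=bool)
    rows = []
    for grp in groups:
        members = np.asarray(grp.members, dtype=int)
        surviving = members[passes_caps[members]]
        if len(surviving) == 0:
            warnings.warn(f"filter group {grp.key!r} empty after hard caps; skipped")
            continue
        med_genes = float(np.median(metrics["n_genes"].to_numpy()[surviving]))
        med_umis = float(np.median(metrics["n_umis"].to_numpy()[surviving]))
        gene_thr = _ladder_threshold(med_genes, cfg.gene_ladder)
        umi_thr = _ladder_threshold(med_umis, cfg.umi_ladder)
        keep = surviving[
            (metrics["n_genes"].to_numpy()[surviving] > gene_thr)
            & (metrics["n_umis"].to_numpy()[surviving] > umi_thr)
        ]
        retained_mask[keep] = True
        rows.append(
            {
                "group": grp.key,
                "n_members": len(members),
                "n_after_caps": len(surviving),
                "median_genes": med_genes,
                "median_umis": med_umis,
                "gene_threshold": gene_thr,
                "umi_threshold": umi_thr,
                "n_retained": len(keep),
            }
        )
    return metrics.index[retained_mask], pd.DataFrame(rows)


def adaptive_min_counts_filter(
    total_counts: np.ndarray,
    n_genes: np.ndarray | None = None,
    start_min_counts: int = 30,
    min_genes: int = 30,
    cfg: QCConfig | None = None,
) -> tuple[np.ndarray, int]:
    """Step-wise minimum-counts escalation for bead-like count data.

    Starting at ``start_min_counts``, the counts threshold is raised by
    ``cfg.adaptive_step`` until the fraction of retained observations with
    total counts below ``cfg.low_quality_counts`` is at most
    ``cfg.max_low_quality_fraction``.  Only the counts threshold escalates;
    the ``min_genes`` requirement stays fixed.

    Returns the retained observation positions and the final threshold.
    Raises ``ValueError`` if the target cannot be reached before the dataset
    empties.
    """
    cfg = cfg or QCConfig()
    total_counts = np.asarray(total_counts)
    base = np.ones(len(total_counts), dtype=bool)
    if n_genes is not None:
        base &= np.asarray(n_genes) >= min_genes
    threshold = int(start_min_counts)
    while True:
        keep = base & (total_counts >= threshold)
        n_keep = int(keep.sum())
        if n_keep == 0:
            raise ValueError(
                "adaptive filter emptied the dataset before reaching the "
                "low-quality-fraction target"
            )
        frac_low = float((total_counts[keep] < cfg.low_quality_counts).mean())
        if frac_low <= cfg.max_low_quality_fraction:
            return np.flatnonzero(keep), threshold
        threshold += cfg.adaptive_step


def sample_gates(
    dataset,
    reference_pseudobulk: pd.Series | None = None,
    cfg: QCConfig | None = None,
) -> dict:
    """Evaluate per-sample pass/fail gates appropriate to the method.

    Bead datasets require mean counts per bead >= 150; segmented molecule-cell
    datasets require mean counts per cell >= 50.  If ``reference_pseudobulk``
    (mean expression per feature, e.g. matched sc/snRNA-seq) is given, the
    Pearson r of log1p mean expression over shared features must be >= 0.60.
    All applicable gates must pass.
    """
    cfg = cfg or QCConfig()
    totals = np.asarray(dataset.values).sum(axis=1)
    mean_counts = float(totals.mean()) if len(totals) else 0.0
    report: dict = {"method": dataset.method, "mean_counts": mean_counts, "gates": {}}

    if dataset.method == "slideseq":
        report["gates"]["mean_counts"] = mean_counts >= cfg.bead_gate_mean_counts
    elif dataset.method in {"merfish_cell", "exseq_cell"}:
        report["gates"]["mean_counts"] = mean_counts >= cfg.molecule_gate_mean_counts

    if reference_pseudobulk is not None:
        mean_expr = pd.Series(
            np.asarray(dataset.values, dtype=float).mean(axis=0), index=dataset.feature_names
        )
        shared = mean_expr.index.intersection(reference_pseudobulk.index)
        if len(shared) == 0:
            raise ValueError("reference pseudobulk shares no features with the dataset")
        r = float(
            pearsonr(
                np.log1p(mean_expr[shared].to_numpy()),
                np.log1p(reference_pseudobulk[shared].to_numpy(dtype=float)),
            ).statistic
        )
        report["pseudobulk_r"] = r
        report["gates"]["pseudobulk_r"] = r >= cfg.pseudobulk_gate_r

    report["pass"] = all(report["gates"].values()) if report["gates"] else True
    return report


def filter_features_min_cells(values: np.ndarray, min_cells: int = 3) -> np.ndarray:
    """Positions of features detected in at least ``min_cells`` observations."""
    detected = (np.asarray(values) > 0).sum(axis=0)
    return np.flatnonzero(detected >= min_cells)
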