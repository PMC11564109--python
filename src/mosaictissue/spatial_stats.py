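"""Spatial statistics: cross-method agreement, co-localization, congruence.

The statistics here quantify how well serial sections of one biopsy, profiled
with different assays, agree on local tissue organization, and how cell types
co-localize in space:

* cell-type composition on a universal 100 x 100-um bin lattice, compared
  across methods by per-bin Pearson correlation;
* distance-resolved co-occurrence: for an anchor type, the log2 ratio of the
  probability of finding each partner type at a given distance relative to
  the unconditional partner probability at that distance (the log-occurrence
  score); summarized per pair as *strength* (first-interval score) and
  *range* (distance at which the score decays to 25% of the strength);
* adjusted Rand index between partitions with bootstrap resampling;
* Pearson contingency ratios (observed over independence-expected counts);
* a baseline compositional annotation transfer by nonnegative least squares
  against reference cell-type centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "CompositionGrid",
    "CoOccurrenceCurve",
    "ColocalizationSummary",
    "grid_bin_composition",
    "cross_method_bin_correlation",
    "co_occurrence",
    "strength_range",
    "ari_congruence",
    "contingency_ratio",
    "transfer_composition",
]


@dataclass
class CompositionGrid:
    """Per-bin cell-type frequency vectors on a universal square lattice.

    ``frequencies`` is indexed by (bin_ix, bin_iy) and has one column per
    cell type seen in any section of the biopsy; rows sum to 1.
    """

    bin_size: float
    frequencies: pd.DataFrame
    counts: pd.Series

    def __post_init__(self) -> None:
        freq = self.frequencies.to_numpy()
        if (freq < 0).any() or not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("bin frequencies must be >= 0 and sum to 1")


@dataclass
class CoOccurrenceCurve:
    """Distance-binned log-occurrence scores for one anchor type."""

    anchor: str
    partners: list[str]
    edges: np.ndarray
    scores: pd.DataFrame  # partners x distance bins

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("distance-bin edges must be strictly increasing")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("scores must be finite")


@dataclass
class ColocalizationSummary:
    anchor: str
    partner: str
    strength: float
    range_um: float
    degenerate: bool = False


def default_edges(max_distance: float = 500.0, n_bins: int = 10) -> np.ndarray:
    """The default distance binning: ``n_bins`` linear bins over [0, max]."""
    return np.linspace(0.0, max_distance, n_bins + 1)


def grid_bin_composition(
    coords: np.ndarray,
    cell_types: np.ndarray,
    bin_size: float = 100.0,
    all_types: list[str] | None = None,
) -> CompositionGrid:
    """Cell-type composition per square bin from categorical labels.

    ``all_types`` fixes the column union (the types seen in any section of the
    biopsy) so grids from different sections are comparable; empty bins are
    excluded.
    """
    coords = np.asarray(coords, dtype=float)
    cell_types = np.asarray(cell_types)
    if len(cell_types) == 0:
        raise ValueError("no labeled observations")
    types = sorted(set(all_types)) if all_types is not None else sorted(set(cell_types))
    ix = np.floor(coords[:, 0] / bin_size).astype(np.int64)
    iy = np.floor(coords[:, 1] / bin_size).astype(np.int64)
    df = pd.DataFrame({"ix": ix, "iy": iy, "type": cell_types})
    counts = df.groupby(["ix", "iy", "type"], observed=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=types, fill_value=0)
    totals = counts.sum(axis=1)
    freq = counts.div(totals, axis=0)
    return CompositionGrid(bin_size=bin_size, frequencies=freq, counts=totals)


def cross_method_bin_correlation(
    grids: list[CompositionGrid],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin Pearson correlation of composition vectors between grid pairs.

    Grids must share the lattice and type union.  Only bins present (non-empty)
    in both sections enter; bins where either composition vector is constant
    have undefined correlation and are excluded but counted.

    Returns ``(per_bin, summary)``: long-format per-bin correlations and one
    row per grid pair with the median r and the number of excluded bins.
    """
    per_bin_rows, summary_rows = [], []
    for i in range(len(grids)):
        for j in range(i + 1, len(grids)):
            a, b = grids[i], grids[j]
            if a.bin_size != b.bin_size or list(a.frequencies.columns) != list(
                b.frequencies.columns
            ):
                raise ValueError("grids must share the universal lattice and type union")
            shared = a.frequencies.index.intersection(b.frequencies.index)
            rs, n_excluded = [], 0
            for bin_id in shared:
                va = a.frequencies.loc[bin_id].to_numpy()
                vb = b.frequencies.loc[bin_id].to_numpy()
                if np.ptp(va) == 0 or np.ptp(vb) == 0:
                    n_excluded += 1
                    continue
                r = float(pearsonr(va, vb).statistic)
                rs.append(r)
                per_bin_rows.append({"pair": (i, j), "bin": bin_id, "r": r})
            summary_rows.append(
                {
                    "pair": (i, j),
                    "n_bins": len(rs),
                    "n_excluded": n_excluded,
                    "median_r": float(np.median(rs)) if rs else np.nan,
                }
            )
    return pd.DataFrame(per_bin_rows), pd.DataFrame(summary_rows)


def _pair_counts(
    coords: np.ndarray, type_codes: np.ndarray, n_types: int, edges: np.ndarray
) -> np.ndarray:
    """Ordered (center, partner, distance-bin) pair counts, grid-accelerated.

    Every unordered pair within the maximum distance contributes twice, once
    per orientation.  Distance bins are half-open ``[lo, hi)`` except the last,
    which is closed at the maximum distance.
    """
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=float(edges[-1]), output_type="ndarray")
    counts = np.zeros((n_types, n_types, len(edges) - 1), dtype=np.int64)
    if len(pairs) == 0:
        return counts
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    k = np.searchsorted(edges, d, side="right") - 1
    k = np.clip(k, 0, len(edges) - 2)  # close the last bin at the max distance
    ti, tj = type_codes[pairs[:, 0]], type_codes[pairs[:, 1]]
    np.add.at(counts, (ti, tj, k), 1)
    np.add.at(counts, (tj, ti, k), 1)
    return counts


def log_occurrence_scores(
    counts: np.ndarray, types: list[str], anchor: str, alpha: float = 1.0, base: float = 2.0
) -> pd.DataFrame:
    """Log-occurrence scores from an ordered pair-count tensor.

    ``score(b, k) = log2[ P(partner=b | center=anchor, bin k)
    / P(partner=b | any center, bin k) ]`` with pseudocount ``alpha`` added to
    every (center, partner, bin) pair count.  This is the *definition* of the
    score; counting may be accelerated but must agree with exhaustive
    enumeration.
    """
    a = types.index(anchor)
    smoothed = counts.astype(float) + alpha
    p_given_anchor = smoothed[a] / smoothed[a].sum(axis=0, keepdims=True)
    pooled = smoothed.sum(axis=0)
    p_any = pooled / pooled.sum(axis=0, keepdims=True)
    scores = np.log(p_given_anchor / p_any) / np.log(base)
    return pd.DataFrame(scores, index=types)


def co_occurrence(
    coords: np.ndarray,
    cell_types: np.ndarray,
    anchor: str,
    edges: np.ndarray | None = None,
    alpha: float = 1.0,
    base: float = 2.0,
    max_obs: int = 50_000,
) -> CoOccurrenceCurve:
    """Distance-resolved co-occurrence of partner types around an anchor type.

    Counts all observation pairs within the maximum distance exactly
    (k-d-tree accelerated; intended for up to ~50k observations) and scores
    them with :func:`log_occurrence_scores`.
    """
    coords = np.asarray(coords, dtype=float)
    cell_types = np.asarray(cell_types)
    if len(coords) > max_obs:
        raise ValueError(f"exact all-pairs counting limited to {max_obs} observations")
    types = sorted(set(cell_types))
    if len(types) < 2:
        raise ValueError("at least two labeled types required")
    if anchor not in types:
        raise ValueError(f"anchor type {anchor!r} absent from the data")
    edges = default_edges() if edges is None else np.asarray(edges, dtype=float)
    code = {t: i for i, t in enumerate(types)}
    type_codes = np.array([code[t] for t in cell_types])
    counts = _pair_counts(coords, type_codes, len(types), edges)
    scores = log_occurrence_scores(counts, types, anchor, alpha=alpha, base=base)
    return CoOccurrenceCurve(anchor=anchor, partners=types, edges=edges, scores=scores)


def strength_range(
    curve: CoOccurrenceCurve, decay_fraction: float = 0.25
) -> list[ColocalizationSummary]:
    """Summarize each (anchor, partner) curve as strength and range.

    Strength is the signed score of the first distance interval (negative
    values indicate exclusion/repulsion).  Range is the center of the first
    interval at which the absolute score has decayed to ``decay_fraction`` of
    the absolute strength, or the maximum distance if it never does.  A zero
    strength makes the range degenerate (first interval center, flagged).
    """
    centers = 0.5 * (curve.edges[:-1] + curve.edges[1:])
    out = []
    for partner in curve.partners:
        scores = curve.scores.loc[partner].to_numpy()
        strength = float(scores[0])
        if strength == 0.0:
            out.append(
                ColocalizationSummary(
                    anchor=curve.anchor,
                    partner=partner,
                    strength=0.0,
                    range_um=float(centers[0]),
                    degenerate=True,
                )
            )
            continue
        decayed = np.abs(scores) <= decay_fraction * abs(strength)
        rng = float(centers[np.argmax(decayed)]) if decayed.any() else float(curve.edges[-1])
        out.append(
            ColocalizationSummary(
                anchor=curve.anchor, partner=partner, strength=strength, range_um=rng
            )
        )
    return out


def ari_congruence(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    n_boot: int = 10,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Adjusted Rand index with bootstrap mean and standard deviation.

    The ARI is the chance-corrected pair-counting agreement between two
    partitions (1 = identical, ~0 = random).  Bootstrap resamples observations
    with replacement ``n_boot`` times and recomputes; returns
    ``(mean, sd, replicates)``.
    """
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, len(labels_a), size=len(labels_a))
        reps[i] = adjusted_rand_score(labels_a[idx], labels_b[idx])
    return float(reps.mean()), float(reps.std(ddof=1)) if n_boot > 1 else 0.0, reps


def contingency_ratio(count_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson contingency ratios: observed over independence-expected counts.

    ``expected[i, j] = row_sum[i] * col_sum[j] / total``; a homogeneous table
    yields all-ones.  Rows and columns must have positive sums.
    """
    obs = count_table.to_numpy(dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("zero row or column sum")
    expected = row * col / obs.sum()
    return pd.DataFrame(obs / expected, index=count_table.index, columns=count_table.columns)


def transfer_composition(
    profiles: np.ndarray,
    centroids: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Baseline compositional annotation transfer by NNLS mixture fitting.

    Each observation profile is decomposed as a nonnegative mixture of
    reference cell-type centroids (``centroids``: types x features, shared
    feature space), renormalized onto the simplex.  All-zero profiles get a
    uniform composition and are flagged.

    Returns (compositions, categorical argmax labels, flags).
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    basis = centroids.to_numpy(dtype=float).T  # features x types
    n_types = basis.shape[1]
    comps = np.empty((profiles.shape[0], n_types))
    flags = np.zeros(profiles.shape[0], dtype=bool)
    for i, prof in enumerate(profiles):
        w, _ = nnls(basis, prof)
        s = w.sum()
        if s <= 0:
            comps[i] = 1.0 / n_types
            flags[i] = True
        else:
            comps[i] = w / s
    comp_df = pd.DataFrame(comps, columns=centroids.index)
    labels = comp_df.idxmax(axis=1)
    return comp_df, labels, flags
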