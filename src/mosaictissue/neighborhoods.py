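"""Signature scoring, spatial EMT phenotypes and neighborhood differentials.

A *signature* (e.g. the 50-gene EMT program, of which 20 genes survive on the
imaging panel) is scored per cell as the mean expression of signature genes
minus the mean of expression-matched control genes.  Malignant-cell scores
aggregated on 100 x 100-um bins drive three analyses:

* classification of each sample into a spatial EMT phenotype (low / patched /
  high) from the mean score and the spatial autocorrelation (Moran's I) of
  bin means — a rule-based surrogate for what is otherwise a manual call;
* *neighborhoods*: bins split at the per-sample median score into EMT-high
  and EMT-low classes (strict comparison; ties unassigned), with differential
  cell-type composition between classes (CLR transform, two-sided rank-sum
  test, Benjamini-Hochberg);
* differential expression between phenotype groups (per-sample position
  splits, CLR-normalized pseudobulks, Welch's t-test) and between malignant
  cells proximal vs distal to T/NK cells (bin co-occupancy flag, rank-sum
  test, per-sample and pooled, with direction-flip reporting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Signature",
    "NeighborhoodLabels",
    "PhenotypeCall",
    "score_signature",
    "bin_mean_scores",
    "morans_i",
    "classify_emt_phenotype",
    "define_neighborhoods",
    "clr_transform",
    "neighborhood_composition_de",
    "phenotype_expression_de",
    "tnk_proximity_de",
    "benjamini_hochberg",
]


@dataclass
class Signature:
    """A named gene program, optionally restricted to an assay panel."""

    name: str
    genes: list[str]

    def restrict(self, panel: list[str]) -> "Signature":
        kept = [g for g in self.genes if g in set(panel)]
        if not kept:
            raise ValueError(f"signature {self.name!r} empty after panel intersection")
        return Signature(name=self.name, genes=kept)


@dataclass
class NeighborhoodLabels:
    """Per-bin neighborhood classes relative to the sample median score."""

    bin_scores: pd.Series  # indexed by (bin_ix, bin_iy)
    median: float
    high: pd.Index
    low: pd.Index
    tied: pd.Index
    degenerate: bool = False


@dataclass
class PhenotypeCall:
    sample: str
    phenotype: str  # low | patched | high
    mean_score: float
    patchiness: float  # Moran's I of bin means
    n_bins: int


def score_signature(
    expression: pd.DataFrame,
    signature: Signature,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Control-matched signature score per observation.

    ``expression`` is log-normalized, observations x genes.  Genes are binned
    into ``n_bins`` equal-size bins of average expression; for each signature
    gene, ``n_ctrl`` control genes are drawn (seeded, without replacement,
    excluding signature genes) from the same bin.  The score is the mean
    expression of the signature genes minus the mean over the pooled control
    set, so a constant added to all genes cancels exactly.
    """
    sig_genes = [g for g in signature.genes if g in expression.columns]
    if not sig_genes:
        raise ValueError("signature has no genes in the expression matrix")
    rng = np.random.default_rng(seed)
    gene_means = expression.mean(axis=0)
    n_bins_eff = min(n_bins, len(gene_means))
    bins = pd.qcut(gene_means.rank(method="first"), n_bins_eff, labels=False)
    sig_set = set(sig_genes)
    controls: set = set()
    for g in sig_genes:
        pool = bins.index[(bins == bins[g]) & ~bins.index.isin(sig_set)]
        if len(pool) == 0:
            continue
        take = min(n_ctrl, len(pool))
        controls.update(rng.choice(pool, size=take, replace=False))
    if not controls:
        raise ValueError("no control genes available outside the signature")
    score = expression[sig_genes].mean(axis=1) - expression[sorted(controls)].mean(axis=1)
    score.name = signature.name
    return score


def bin_mean_scores(
    coords: np.ndarray, scores: np.ndarray, bin_size: float = 100.0
) -> pd.Series:
    """Mean score per square bin (lattice anchored at the origin)."""
    coords = np.asarray(coords, dtype=float)
    ix = np.floor(coords[:, 0] / bin_size).astype(np.int64)
    iy = np.floor(coords[:, 1] / bin_size).astype(np.int64)
    return pd.Series(np.asarray(scores, dtype=float)).groupby([ix, iy]).mean()


def morans_i(bin_values: pd.Series) -> float:
    """Moran's I with queen contiguity on an occupied square-bin lattice.

    Neighbors are the up-to-eight surrounding bins (binary weights).  Returns
    0.0 when no bin has a neighbor or the values are constant.
    """
    idx = {b: i for i, b in enumerate(bin_values.index)}
    z = bin_values.to_numpy(dtype=float)
    z = z - z.mean()
    denom = (z**2).sum()
    if denom == 0:
        return 0.0
    num = 0.0
    w_total = 0
    for (bx, by), i in idx.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                j = idx.get((bx + dx, by + dy))
                if j is not None:
                    num += z[i] * z[j]
                    w_total += 1
    if w_total == 0:
        return 0.0
    return float(len(z) / w_total * num / denom)


def classify_emt_phenotype(
    coords: np.ndarray,
    scores: np.ndarray,
    sample: str = "sample",
    bin_size: float = 100.0,
    theta_low: float = -0.1,
    theta_high: float = 0.4,
    theta_moran: float = 0.3,
    min_bins: int = 10,
) -> PhenotypeCall:
    """Rule-based spatial EMT phenotype call for one sample.

    The sample mean score ``m`` and the patchiness ``pi`` (Moran's I of the
    100-um bin means) decide the class: high if ``m > theta_high``, low if
    ``m < theta_low``, otherwise patched if ``pi > theta_moran`` else the
    nearer of high/low.  Thresholds are configurable; the defaults are
    surrogates for a manual assignment.
    """
    scores = np.asarray(scores, dtype=float)
    bins = bin_mean_scores(coords, scores, bin_size)
    if len(bins) < min_bins:
        raise ValueError(f"only {len(bins)} non-empty bins (< {min_bins}); unclassifiable")
    m = float(scores.mean())
    pi = morans_i(bins)
    if m > theta_high:
        phenotype = "high"
    elif m < theta_low:
        phenotype = "low"
    elif pi > theta_moran:
        phenotype = "patched"
    else:
        phenotype = "high" if abs(m - theta_high) <= abs(m - theta_low) else "low"
    return PhenotypeCall(
        sample=sample, phenotype=phenotype, mean_score=m, patchiness=pi, n_bins=len(bins)
    )


def define_neighborhoods(bin_scores: pd.Series) -> NeighborhoodLabels:
    """Split bins into EMT-high / EMT-low at the per-sample median score.

    Comparisons are strict; bins exactly at the median are unassigned.  If all
    bins tie, both classes are empty and the result is flagged degenerate.
    """
    med = float(bin_scores.median())
    high = bin_scores.index[bin_scores > med]
    low = bin_scores.index[bin_scores < med]
    tied = bin_scores.index[bin_scores == med]
    degenerate = len(high) == 0 and len(low) == 0
    if degenerate:
        warnings.warn("all bins tied at the median; neighborhood classes are empty")
    return NeighborhoodLabels(
        bin_scores=bin_scores, median=med, high=high, low=low, tied=tied, degenerate=degenerate
    )


def clr_transform(proportions: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Center log-ratio transform of a compositions table (rows sum to 1).

    Zero proportions are offset by ``pseudocount`` (default: half the smallest
    nonzero proportion in the table) before renormalization; each output row
    sums to 0.
    """
    props = proportions.to_numpy(dtype=float)
    if pseudocount is None:
        nonzero = props[props > 0]
        if nonzero.size == 0:
            raise ValueError("all-zero composition table")
        pseudocount = float(nonzero.min()) / 2.0
    shifted = props + pseudocount
    shifted = shifted / shifted.sum(axis=1, keepdims=True)
    logp = np.log(shifted)
    clr = logp - logp.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=proportions.index, columns=proportions.columns)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must be in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def neighborhood_composition_de(
    compositions: pd.DataFrame,
    labels: NeighborhoodLabels,
    min_bins_per_class: int = 3,
) -> pd.DataFrame:
    """Differential cell-type composition between EMT-high and EMT-low bins.

    ``compositions``: bins x types proportions on the same bin index as the
    labels.  Per type: CLR values are compared between classes with a
    two-sided rank-sum (Mann-Whitney) test, BH-corrected across types; the
    log-FC column is the difference of mean CLR values (high minus low).
    """
    high = labels.high.intersection(compositions.index)
    low = labels.low.intersection(compositions.index)
    if len(high) < min_bins_per_class or len(low) < min_bins_per_class:
        raise ValueError(f"need >= {min_bins_per_class} bins per neighborhood class")
    clr = clr_transform(compositions)
    rows = []
    for t in compositions.columns:
        hi, lo = clr.loc[high, t].to_numpy(), clr.loc[low, t].to_numpy()
        if np.ptp(np.concatenate([hi, lo])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue)
        rows.append({"cell_type": t, "log_fc": float(hi.mean() - lo.mean()), "p": p})
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def _position_split_pseudobulks(
    expression: pd.DataFrame, coords: np.ndarray, n_splits: int = 2
) -> list[np.ndarray]:
    """Mean pseudobulk per equal-extent y-axis slice of one sample."""
    y = np.asarray(coords, dtype=float)[:, 1]
    edges = np.linspace(y.min(), y.max() + 1e-9, n_splits + 1)
    parts = []
    for k in range(n_splits):
        mask = (y >= edges[k]) & (y < edges[k + 1])
        if mask.sum() > 0:
            parts.append(expression.loc[mask].mean(axis=0).to_numpy())
    return parts


def phenotype_expression_de(
    samples: dict[str, dict],
    group_a: list[str],
    group_b: list[str],
    n_splits: int = 2,
) -> pd.DataFrame:
    """Differential expression between phenotype groups of samples.

    ``samples`` maps sample id to ``{"expression": obs x genes DataFrame,
    "coords": (n, 2)}``.  Each sample is split into ``n_splits`` equal-extent
    parts along y to capture within-sample variability; per split the mean
    pseudobulk is CLR-normalized across genes; per gene a two-sided Welch's
    t-test compares the group-A splits against the group-B splits, with BH
    correction across genes.  Both directions are implied by the signed
    log-FC (mean CLR difference, A minus B).
    """
    genes = None
    split_profiles: dict[str, list[np.ndarray]] = {"a": [], "b": []}
    for grp, names in (("a", group_a), ("b", group_b)):
        for name in names:
            s = samples[name]
            expr = s["expression"]
            genes = list(expr.columns) if genes is None else genes
            split_profiles[grp].extend(_position_split_pseudobulks(expr, s["coords"], n_splits))
    if len(split_profiles["a"]) < 2 or len(split_profiles["b"]) < 2:
        raise ValueError("each group needs at least two sample splits")
    a = pd.DataFrame(split_profiles["a"], columns=genes)
    b = pd.DataFrame(split_profiles["b"], columns=genes)
    a_clr = clr_transform(a.div(a.sum(axis=1), axis=0))
    b_clr = clr_transform(b.div(b.sum(axis=1), axis=0))
    rows = []
    for g in genes:
        av, bv = a_clr[g].to_numpy(), b_clr[g].to_numpy()
        if np.ptp(np.concatenate([av, bv])) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(av, bv, equal_var=False).pvalue)
        rows.append({"gene": g, "log_fc": float(av.mean() - bv.mean()), "p": p})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def tnk_proximity_de(
    expression: pd.DataFrame,
    coords: np.ndarray,
    cell_types: np.ndarray,
    sample_ids: np.ndarray,
    malignant_label: str = "malignant",
    tnk_labels: tuple[str, ...] = ("tnk", "T", "NK", "T/NK"),
    bin_size: float = 100.0,
) -> dict:
    """Expression differences between T/NK-proximal and -distal malignant cells.

    A malignant cell is *proximal* iff its 100 x 100-um bin contains at least
    one T or NK cell.  Per gene, a two-sided rank-sum test compares proximal
    vs distal malignant cells, BH-corrected; the analysis runs per sample and
    pooled across samples.  Samples without T/NK cells or without distal
    malignant cells are skipped with a flag.  Genes whose log-FC direction
    differs between the pooled result and any per-sample result are reported
    (patient-specific signals can oppose or even invert the common one).

    Returns ``{"per_sample": {sample: DataFrame}, "pooled": DataFrame,
    "skipped": [sample, ...], "direction_flips": [gene, ...]}``.
    """
    coords = np.asarray(coords, dtype=float)
    cell_types = np.asarray(cell_types)
    sample_ids = np.asarray(sample_ids)
    tnk_set = set(tnk_labels)

    def run(mask: np.ndarray) -> pd.DataFrame | None:
        sub_coords = coords[mask]
        sub_types = cell_types[mask]
        ix = np.floor(sub_coords[:, 0] / bin_size).astype(np.int64)
        iy = np.floor(sub_coords[:, 1] / bin_size).astype(np.int64)
        bin_id = pd.MultiIndex.from_arrays([ix, iy])
        tnk_bins = set(bin_id[np.isin(sub_types, list(tnk_set))])
        malignant = sub_types == malignant_label
        proximal = malignant & np.array([b in tnk_bins for b in bin_id])
        distal = malignant & ~proximal
        if proximal.sum() == 0 or distal.sum() == 0:
            return None
        expr = expression.loc[mask]
        rows = []
        for g in expression.columns:
            pv_, dv = expr.loc[proximal, g].to_numpy(), expr.loc[distal, g].to_numpy()
            if np.ptp(np.concatenate([pv_, dv])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(pv_, dv, alternative="two-sided").pvalue)
            rows.append({"gene": g, "log_fc": float(pv_.mean() - dv.mean()), "p": p})
        out = pd.DataFrame(rows).set_index("gene")
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        return out

    per_sample, skipped = {}, []
    for s in pd.unique(sample_ids):
        res = run(sample_ids == s)
        if res is None:
            skipped.append(str(s))
        else:
            per_sample[str(s)] = res
    pooled = run(np.ones(len(coords), dtype=bool))
    flips = []
    if pooled is not None:
        for g in pooled.index:
            pooled_dir = np.sign(pooled.loc[g, "log_fc"])
            for res in per_sample.values():
                if pooled_dir != 0 and np.sign(res.loc[g, "log_fc"]) == -pooled_dir:
                    flips.append(g)
                    break
    return {
        "per_sample": per_sample,
        "pooled": pooled,
        "skipped": skipped,
        "direction_flips": flips,
    }
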