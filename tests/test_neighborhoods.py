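import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from mosaictissue.neighborhoods import (
    Signature,
    benjamini_hochberg,
    bin_mean_scores,
    classify_emt_phenotype,
    clr_transform,
    define_neighborhoods,
    morans_i,
    neighborhood_composition_de,
    phenotype_expression_de,
    score_signature,
    tnk_proximity_de,
)

EMT_PANEL_20 = [
    "TCF4", "COL4A1", "BGN", "COL1A2", "FN1", "COL1A1", "ACTA2", "MYL9",
    "HSPG2", "TIMP1", "VIM", "THY1", "APOE", "COL3A1", "DCN", "LUM",
    "TAGLN", "TPM2", "GNG11", "COL4A2",
]
EMT_50 = EMT_PANEL_20 + [f"EMT_EXTRA{i:02d}" for i in range(30)]


def random_expression(n_obs, genes, rng, shift_genes=(), shift=0.0):
    base = rng.normal(1.0, 0.3, size=(n_obs, len(genes)))
    df = pd.DataFrame(base, columns=genes)
    for g in shift_genes:
        df[g] += shift
    return df


class TestScoreSignature:
    def test_null_signature_scores_near_zero(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(300)]
        sig = Signature("null", genes[:20])
        expr = random_expression(5_000, genes, rng)
        score = score_signature(expr, sig, seed=0)
        assert abs(score.mean()) < 0.02

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:03d}" for i in range(300)]
        sig_genes = genes[:20]
        expr = random_expression(3_000, genes, rng, shift_genes=sig_genes, shift=1.0)
        score = score_signature(expr, Signature("sig", sig_genes), seed=0)
        assert score.mean() == pytest.approx(1.0, abs=0.05)

    def test_panel_restriction_keeps_twenty_genes(self):
        sig = Signature("emt", EMT_50)
        restricted = sig.restrict(EMT_PANEL_20 + ["OTHER1", "OTHER2"])
        assert sorted(restricted.genes) == sorted(EMT_PANEL_20)
        with pytest.raises(ValueError, match="empty after panel"):
            sig.restrict(["OTHER1"])

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(200)]
        expr = random_expression(500, genes, rng)
        sig = Signature("s", genes[:10])
        a = score_signature(expr, sig, seed=3)
        b = score_signature(expr + 5.0, sig, seed=3)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_empty_intersection_rejected(self):
        rng = np.random.default_rng(3)
        expr = random_expression(10, ["a", "b"], rng)
        with pytest.raises(ValueError):
            score_signature(expr, Signature("s", ["zz"]))


class TestNeighborhoods:
    def test_strict_median_split_leaves_median_bin_unassigned(self):
        scores = pd.Series(
            [0.1, 0.2, 0.3],
            index=pd.MultiIndex.from_tuples([(0, 0), (0, 1), (1, 0)]),
        )
        labels = define_neighborhoods(scores)
        assert list(labels.high) == [(1, 0)]
        assert list(labels.low) == [(0, 0)]
        assert list(labels.tied) == [(0, 1)]

    def test_partition_covers_all_bins(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(
            rng.normal(size=60),
            index=pd.MultiIndex.from_tuples([(i, 0) for i in range(60)]),
        )
        labels = define_neighborhoods(scores)
        assert len(labels.high) + len(labels.low) + len(labels.tied) == 60

    def test_all_tied_is_degenerate(self):
        scores = pd.Series(
            [0.5] * 4, index=pd.MultiIndex.from_tuples([(i, 0) for i in range(4)])
        )
        with pytest.warns(UserWarning, match="tied"):
            labels = define_neighborhoods(scores)
        assert labels.degenerate
        assert len(labels.high) == len(labels.low) == 0

    def test_planted_two_level_field_recovered_exactly(self):
        rng = np.random.default_rng(5)
        idx = pd.MultiIndex.from_tuples([(i, j) for i in range(10) for j in range(10)])
        planted = np.array([i < 5 for i, _ in idx])
        scores = pd.Series(np.where(planted, 1.0, -1.0), index=idx)
        labels = define_neighborhoods(scores)
        assert set(labels.high) == set(idx[planted])
        assert set(labels.low) == set(idx[~planted])


class TestPhenotypeClassification:
    def test_constant_field_has_no_autocorrelation(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 2000, size=(3_000, 2))
        scores = 0.2 + rng.normal(0, 0.05, size=3_000)
        call = classify_emt_phenotype(coords, scores)
        assert abs(call.patchiness) < 0.15
        assert call.phenotype != "patched"

    def test_uniform_high_field_classified_high(self):
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            coords = rng.uniform(0, 2000, size=(2_000, 2))
            scores = 1.0 + rng.normal(0, 0.3, size=2_000)
            call = classify_emt_phenotype(coords, scores)
            successes += call.phenotype == "high"
        assert successes >= 18

    def test_planted_discs_classified_patched(self):
        successes = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            coords = rng.uniform(0, 2000, size=(3_000, 2))
            centers = rng.uniform(300, 1700, size=(3, 2))
            inside = (
                np.linalg.norm(coords[:, None] - centers[None], axis=2) < 300
            ).any(axis=1)
            scores = np.where(inside, 1.2, -0.15) + rng.normal(0, 0.3, size=3_000)
            call = classify_emt_phenotype(coords, scores)
            successes += call.phenotype == "patched"
        assert successes >= 18

    def test_too_few_bins_unclassifiable(self):
        coords = np.zeros((50, 2))
        with pytest.raises(ValueError, match="unclassifiable"):
            classify_emt_phenotype(coords, np.zeros(50))


class TestMoransI:
    def test_alternating_columns_are_negative(self):
        # under queen contiguity 6 of 8 neighbors of a striped cell differ
        idx = pd.MultiIndex.from_tuples([(i, j) for i in range(8) for j in range(8)])
        vals = pd.Series([i % 2 for i, _ in idx], index=idx, dtype=float)
        assert morans_i(vals) < -0.3

    def test_smooth_gradient_is_positive(self):
        idx = pd.MultiIndex.from_tuples([(i, j) for i in range(8) for j in range(8)])
        vals = pd.Series([float(i) for i, _ in idx], index=idx)
        assert morans_i(vals) > 0.5

    def test_constant_field_returns_zero(self):
        idx = pd.MultiIndex.from_tuples([(i, 0) for i in range(5)])
        assert morans_i(pd.Series([1.0] * 5, index=idx)) == 0.0


class TestCLR:
    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(7)
        props = rng.dirichlet(np.ones(6), size=40)
        clr = clr_transform(pd.DataFrame(props))
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-9)

    def test_zeros_handled_by_pseudocount(self):
        props = pd.DataFrame([[0.5, 0.5, 0.0], [0.2, 0.3, 0.5]])
        clr = clr_transform(props)
        assert np.isfinite(clr.to_numpy()).all()


class TestBenjaminiHochberg:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_matches_reference_implementation_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(1_000):
            p = rng.uniform(size=rng.integers(1, 30))
            ours = benjamini_hochberg(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def make_labels(idx_high, idx_low):
    import mosaictissue.neighborhoods as nb

    all_idx = idx_high.append(idx_low)
    scores = pd.Series(
        [1.0] * len(idx_high) + [-1.0] * len(idx_low), index=all_idx
    )
    return nb.NeighborhoodLabels(
        bin_scores=scores,
        median=0.0,
        high=idx_high,
        low=idx_low,
        tied=all_idx[:0],
    )


class TestCompositionDE:
    def _bins(self, n):
        return pd.MultiIndex.from_tuples([(i, 0) for i in range(n)])

    def test_null_compositions_rarely_significant(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            props = rng.dirichlet(np.ones(5) * 4, size=60)
            comps = pd.DataFrame(props, index=self._bins(60))
            labels = make_labels(self._bins(60)[:30], self._bins(60)[30:])
            res = neighborhood_composition_de(comps, labels)
            hits += int((res["q"] < 0.05).any())
        assert hits <= 4  # ~5% familywise rate under the null

    def test_planted_fibroblast_enrichment_recovered(self):
        rng = np.random.default_rng(10)
        types = ["malignant", "fibroblast", "macrophage", "tnk"]
        base = rng.dirichlet([10, 4, 3, 2], size=200)
        high = base[:100].copy()
        high[:, 1] += 0.25
        high /= high.sum(axis=1, keepdims=True)
        comps = pd.DataFrame(
            np.vstack([high, base[100:]]), index=self._bins(200), columns=types
        )
        labels = make_labels(self._bins(200)[:100], self._bins(200)[100:])
        res = neighborhood_composition_de(comps, labels)
        assert res.loc["fibroblast", "q"] < 0.05
        assert res.loc["fibroblast", "log_fc"] > 0

    def test_too_few_bins_per_class_rejected(self):
        comps = pd.DataFrame(
            np.full((4, 2), 0.5), index=self._bins(4), columns=["a", "b"]
        )
        labels = make_labels(self._bins(4)[:2], self._bins(4)[2:])
        with pytest.raises(ValueError, match="bins per neighborhood class"):
            neighborhood_composition_de(comps, labels)


def make_sample(rng, n_cells, genes, shift_genes=(), shift=0.0):
    coords = rng.uniform(0, 1000, size=(n_cells, 2))
    gene_means = np.linspace(0.5, 3.0, len(genes))  # shared across samples
    expr = pd.DataFrame(
        rng.gamma(2.0, gene_means / 2.0, size=(n_cells, len(genes))), columns=genes
    )
    for g in shift_genes:
        expr[g] *= np.exp(shift)
    return {"expression": expr, "coords": coords}


class TestPhenotypeExpressionDE:
    GENES = [f"g{i:02d}" for i in range(30)]

    def test_null_groups_rarely_significant(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            samples = {
                f"s{i}": make_sample(rng, 150, self.GENES) for i in range(8)
            }
            res = phenotype_expression_de(
                samples, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
            )
            hits += int((res["q"] < 0.05).any())
        assert hits <= 4

    def test_planted_twofold_gene_recovered(self):
        rng = np.random.default_rng(12)
        samples = {}
        for i in range(8):
            samples[f"a{i}"] = make_sample(
                rng, 200, self.GENES, shift_genes=["g00"], shift=np.log(2)
            )
        for i in range(8):
            samples[f"b{i}"] = make_sample(rng, 200, self.GENES)
        res = phenotype_expression_de(
            samples, [f"a{i}" for i in range(8)], [f"b{i}" for i in range(8)]
        )
        assert res.loc["g00", "q"] < 0.05
        assert res.loc["g00", "log_fc"] > 0

    def test_homogeneous_sample_splits_correlate(self):
        rng = np.random.default_rng(13)
        from mosaictissue.neighborhoods import _position_split_pseudobulks

        s = make_sample(rng, 2_000, self.GENES)
        parts = _position_split_pseudobulks(s["expression"], s["coords"])
        assert len(parts) == 2
        assert np.corrcoef(parts[0], parts[1])[0, 1] > 0.95

    def test_single_split_group_rejected(self):
        rng = np.random.default_rng(14)
        samples = {"a": make_sample(rng, 50, self.GENES)}
        with pytest.raises(ValueError):
            phenotype_expression_de(samples, ["a"], [])


class TestTnkProximityDE:
    GENES = [f"g{i:02d}" for i in range(20)]

    def _tissue(self, rng, n=800, with_tnk=True, shift_genes=(), shift=0.0):
        coords = rng.uniform(0, 1000, size=(n, 2))
        types = np.array(["malignant"] * n, dtype=object)
        if with_tnk:
            types[rng.choice(n, size=n // 10, replace=False)] = "tnk"
        expr = pd.DataFrame(
            rng.normal(1.0, 0.3, size=(n, len(self.GENES))), columns=self.GENES
        )
        if shift_genes:
            ix = np.floor(coords[:, 0] / 100).astype(int)
            iy = np.floor(coords[:, 1] / 100).astype(int)
            key = [(a, b) for a, b in zip(ix, iy)]
            tnk_bins = {k for k, t in zip(key, types) if t == "tnk"}
            proximal = np.array([k in tnk_bins for k in key]) & (types == "malignant")
            for g in shift_genes:
                expr.loc[proximal, g] += shift
        return expr, coords, types

    def test_no_tnk_cells_skips_all_samples(self):
        rng = np.random.default_rng(15)
        expr, coords, types = self._tissue(rng, with_tnk=False)
        res = tnk_proximity_de(
            expr, coords, types, np.array(["s1"] * len(types))
        )
        assert res["skipped"] == ["s1"]
        assert res["pooled"] is None

    def test_planted_mhc_like_shift_recovered(self):
        rng = np.random.default_rng(16)
        expr, coords, types = self._tissue(
            rng, n=2_000, shift_genes=["g00", "g01"], shift=0.5
        )
        res = tnk_proximity_de(expr, coords, types, np.array(["s1"] * len(types)))
        pooled = res["pooled"]
        assert pooled.loc["g00", "q"] < 0.05 and pooled.loc["g00", "log_fc"] > 0
        assert pooled.loc["g01", "q"] < 0.05 and pooled.loc["g01", "log_fc"] > 0

    def test_simpsons_paradox_direction_flip_reported(self):
        # two patients whose within-sample effect is negative, but whose
        # baselines make the pooled effect positive
        rng = np.random.default_rng(17)
        frames, all_coords, all_types, all_samples = [], [], [], []
        for sample, baseline, n_prox_frac, x_off in (
            ("pA", 0.0, 0.1, 0.0),
            ("pB", 3.0, 0.9, 2_000.0),  # disjoint in space so bins never mix
        ):
            n = 600
            coords = rng.uniform(0, 1000, size=(n, 2))
            coords[:, 0] += x_off
            ix = np.floor(coords[:, 0] / 100).astype(int)
            iy = np.floor(coords[:, 1] / 100).astype(int)
            bins = sorted({(a, b) for a, b in zip(ix, iy)})
            n_tnk_bins = int(len(bins) * n_prox_frac)
            tnk_bins = set(bins[:n_tnk_bins])
            proximal = np.array([(a, b) in tnk_bins for a, b in zip(ix, iy)])
            types = np.array(["malignant"] * n, dtype=object)
            # mark one cell per T/NK bin as tnk so the flag fires
            for tb in tnk_bins:
                hits = np.flatnonzero((ix == tb[0]) & (iy == tb[1]))
                types[hits[0]] = "tnk"
            expr = pd.DataFrame(
                rng.normal(baseline, 0.1, size=(n, 1)), columns=["g00"]
            )
            expr.loc[proximal, "g00"] -= 0.3  # within-sample: proximal lower
            frames.append(expr)
            all_coords.append(coords)
            all_types.append(types)
            all_samples += [sample] * n
        expr = pd.concat(frames, ignore_index=True)
        coords = np.vstack(all_coords)
        types = np.concatenate(all_types)
        res = tnk_proximity_de(expr, coords, types, np.array(all_samples))
        pooled_dir = np.sign(res["pooled"].loc["g00", "log_fc"])
        per_dirs = {
            s: np.sign(r.loc["g00", "log_fc"]) for s, r in res["per_sample"].items()
        }
        assert pooled_dir > 0
        assert all(d < 0 for d in per_dirs.values())
        assert "g00" in res["direction_flips"]
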