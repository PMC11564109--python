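import numpy as np
import pandas as pd
import pytest

from mosaictissue import synthetic_data as syn
from mosaictissue.barcodes_probes import build_merfish_codebook


@pytest.fixture(scope="session")
def full_codebook():
    """The production-size constant-weight codebook (291 genes plus blanks)."""
    return build_merfish_codebook(n_genes=291, n_blanks_requested=94, seed=1)


@pytest.fixture(scope="session")
def small_codebook():
    """A quick codebook on a shorter word length for unit tests."""
    return build_merfish_codebook(
        n_genes=30, n_blanks_requested=5, seed=1, length=14, weight=4, min_distance=4
    )


@pytest.fixture(scope="session")
def short_range_truth():
    """Cell map with T/NK cells planted within 20 um of macrophages."""
    truth = syn.generate_cell_map(
        4_000, pattern="short_range", seed=11, anchor_type="macrophage",
        partner_type="tnk", radius=20.0,
    )
    return syn.simulate_expression(truth, seed=11)


@pytest.fixture(scope="session")
def intermixed_truth():
    truth = syn.generate_cell_map(4_000, pattern="intermixed", seed=5)
    return syn.simulate_expression(truth, seed=5)


def brute_force_pair_counts(coords, type_codes, n_types, edges):
    """O(n^2) pair counting oracle: full distance matrix, no acceleration."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    counts = np.zeros((n_types, n_types, len(edges) - 1), dtype=np.int64)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > edges[-1]:
                continue
            k = int(np.searchsorted(edges, d[i, j], side="right")) - 1
            k = min(k, len(edges) - 2)
            counts[type_codes[i], type_codes[j], k] += 1
            counts[type_codes[j], type_codes[i], k] += 1
    return counts


def log_expression_dataframe(dataset):
    """log1p-normalized expression table from a count-mode dataset."""
    vals = np.asarray(dataset.values, dtype=float)
    totals = vals.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = vals / totals * np.median(totals)
    return pd.DataFrame(np.log1p(norm), columns=dataset.feature_names)
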