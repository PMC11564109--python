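"""Synthetic multi-method serial-section generator with known ground truth.

The generator emulates what the analysis pipeline sees in practice: one
tissue (a shared cell map with types, positions, patient-specific malignant
profiles and planted spatial patterns) profiled by several assays on serial
sections, each with its own capture model (panel subsetting, capture
efficiency, molecule scatter, 10-um bead aggregation, intensity
transformation) and per-section rigid perturbation.  Every planted quantity —
interaction radius, patch masks, effect sizes, patient shifts, section
transforms — is recorded in :class:`GroundTruth` so each pipeline stage can be
tested for recovery.

Counts are Poisson around ``efficiency * exp(expected log-expression)``
(negative-binomial overdispersion available via ``MethodProfile.nb_alpha``);
spatial patterns are simple marked point processes (independent uniform,
short-range cluster process, long-range islands).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import MoleculeTable, RigidTransform, SpatialDataset

__all__ = [
    "GroundTruth",
    "MethodProfile",
    "generate_cell_map",
    "simulate_expression",
    "emulate_method",
    "emulate_serial_sections",
]


@dataclass
class GroundTruth:
    """Planted cell map, expression model and pattern parameters."""

    positions: np.ndarray  # (n, 2) um
    cell_types: np.ndarray  # (n,) str
    extent: tuple[float, float]
    pattern: dict
    seed: int
    patient: str = "p0"
    # expression model (filled by simulate_expression)
    genes: list[str] = field(default_factory=list)
    base_profiles: dict = field(default_factory=dict)  # type -> (G,) log-lambda
    patient_shift: np.ndarray | None = None  # (G,), malignant cells only
    signature_genes: list[str] = field(default_factory=list)
    signature_loading: np.ndarray | None = None  # (G,)
    signature_field: np.ndarray | None = None  # (n,)
    field_spec: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_types)

    def expected_log_expression(self) -> np.ndarray:
        """Per-cell expected log-expression: type profile + patient shift
        (malignant only) + signature loading x field value."""
        if not self.genes:
            raise ValueError("no expression model; call simulate_expression first")
        log_e = np.stack([self.base_profiles[t] for t in self.cell_types])
        malignant = self.cell_types == "malignant"
        if self.patient_shift is not None:
            log_e[malignant] += self.patient_shift
        if self.signature_loading is not None and self.signature_field is not None:
            log_e += np.outer(self.signature_field, self.signature_loading)
        return log_e

    def to_json(self, path) -> None:
        payload = {
            "positions": self.positions.tolist(),
            "cell_types": self.cell_types.tolist(),
            "extent": list(self.extent),
            "pattern": self.pattern,
            "seed": self.seed,
            "patient": self.patient,
            "genes": self.genes,
            "base_profiles": {t: v.tolist() for t, v in self.base_profiles.items()},
            "patient_shift": None if self.patient_shift is None else self.patient_shift.tolist(),
            "signature_genes": self.signature_genes,
            "signature_loading": None
            if self.signature_loading is None
            else self.signature_loading.tolist(),
            "signature_field": None
            if self.signature_field is None
            else self.signature_field.tolist(),
            "field_spec": self.field_spec,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class MethodProfile:
    """Capture model of one profiling method.

    ``observation_model``: ``cell`` (counts at cell centers), ``bead``
    (molecules captured by 10-um beads on a square grid, footprint radius
    ``bead_radius``; molecules outside every footprint are lost), ``bin``
    (molecules aggregated on a 10-um lattice) or ``intensity`` (noisy linear
    transform of a marker subset, non-count).
    """

    method: str
    observation_model: str = "cell"
    panel: list[str] | None = None  # None = whole transcriptome
    efficiency: float = 1.0
    scatter_sd: float = 2.0  # um, molecule scatter around the cell center
    intensity_noise_sd: float = 0.1
    intensity_scale: float = 1.0
    bead_spacing: float = 10.0
    bead_radius: float = 5.0
    bin_size: float = 10.0
    nb_alpha: float = 0.0  # gamma-Poisson overdispersion; 0 = pure Poisson

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")
        if self.scatter_sd < 0:
            raise ValueError("scatter sd must be >= 0")
        if self.observation_model not in {"cell", "bead", "bin", "intensity"}:
            raise ValueError(f"unknown observation model {self.observation_model!r}")


DEFAULT_PROPORTIONS = {
    "malignant": 0.5,
    "fibroblast": 0.2,
    "macrophage": 0.15,
    "tnk": 0.1,
    "endothelial": 0.05,
}


def generate_cell_map(
    n_cells: int = 10_000,
    proportions: dict[str, float] | None = None,
    pattern: str = "intermixed",
    seed: int = 0,
    extent: tuple[float, float] = (3_000.0, 3_000.0),
    patient: str = "p0",
    **pattern_params,
) -> GroundTruth:
    """Generate a planted cell map on a rectangular tissue.

    Patterns
    --------
    ``intermixed``
        All types placed independently and uniformly (complete spatial
        randomness between types).
    ``short_range``
        ``partner_type`` cells placed within ``radius`` um (uniform in a
        disc) of randomly chosen ``anchor_type`` cells; other types uniform.
    ``long_range_islands``
        ``island_type`` cells confined to ``n_islands`` discs of
        ``island_radius`` um; other types uniform.
    """
    proportions = dict(proportions or DEFAULT_PROPORTIONS)
    total = sum(proportions.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("type proportions must sum to 1")
    rng = np.random.default_rng(seed)
    types = sorted(proportions)
    counts = rng.multinomial(n_cells, [proportions[t] / total for t in types])
    cell_types = np.repeat(types, counts)
    positions = rng.uniform([0, 0], extent, size=(n_cells, 2))
    info: dict = {"name": pattern}

    if pattern == "intermixed":
        pass
    elif pattern == "short_range":
        anchor = pattern_params.get("anchor_type", "macrophage")
        partner = pattern_params.get("partner_type", "tnk")
        radius = float(pattern_params.get("radius", 20.0))
        info.update({"anchor_type": anchor, "partner_type": partner, "radius": radius})
        anchors = positions[cell_types == anchor]
        if len(anchors) == 0:
            raise ValueError(f"pattern needs at least one {anchor!r} cell")
        idx = np.flatnonzero(cell_types == partner)
        choice = rng.integers(0, len(anchors), size=len(idx))
        ang = rng.uniform(0, 2 * np.pi, size=len(idx))
        rad = radius * np.sqrt(rng.uniform(0, 1, size=len(idx)))
        positions[idx] = anchors[choice] + np.column_stack(
            [rad * np.cos(ang), rad * np.sin(ang)]
        )
        positions[idx] = np.clip(positions[idx], [0, 0], extent)
    elif pattern == "long_range_islands":
        island_type = pattern_params.get("island_type", "macrophage")
        island_radius = float(pattern_params.get("island_radius", 200.0))
        n_islands = int(pattern_params.get("n_islands", 5))
        centers = rng.uniform(
            [island_radius, island_radius],
            [extent[0] - island_radius, extent[1] - island_radius],
            size=(n_islands, 2),
        )
        info.update(
            {
                "island_type": island_type,
                "island_radius": island_radius,
                "n_islands": n_islands,
                "island_centers": centers.tolist(),
            }
        )
        idx = np.flatnonzero(cell_types == island_type)
        choice = rng.integers(0, n_islands, size=len(idx))
        ang = rng.uniform(0, 2 * np.pi, size=len(idx))
        rad = island_radius * np.sqrt(rng.uniform(0, 1, size=len(idx)))
        positions[idx] = centers[choice] + np.column_stack(
            [rad * np.cos(ang), rad * np.sin(ang)]
        )
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    perm = rng.permutation(n_cells)
    return GroundTruth(
        positions=positions[perm],
        cell_types=cell_types[perm],
        extent=extent,
        pattern=info,
        seed=seed,
        patient=patient,
    )


def simulate_expression(
    truth: GroundTruth,
    n_background_genes: int = 30,
    markers_per_type: int = 3,
    n_signature_genes: int = 10,
    signature_field: str = "constant_low",
    signature_effect: float = 1.0,
    patient_shift_sd: float = 0.5,
    base_level: float = -1.0,
    marker_level: float = 1.5,
    n_patches: int = 4,
    patch_radius: float = 400.0,
    seed: int = 0,
) -> GroundTruth:
    """Attach an expression model and a planted signature field to a cell map.

    Genes are ``markers_per_type`` markers per cell type (elevated log-level
    in their own type), ``n_background_genes`` shared background genes and
    ``n_signature_genes`` program genes carried by malignant cells with
    loading ``signature_effect``.  Malignant cells additionally receive a
    patient-specific shift drawn N(0, ``patient_shift_sd``) per gene (seeded
    by the patient id so different patients separate).

    ``signature_field`` options: ``constant_low`` (0 everywhere),
    ``constant_high`` (1 on malignant cells), ``patched`` (1 inside
    ``n_patches`` planted discs of ``patch_radius`` um, 0 outside).
    """
    rng = np.random.default_rng(seed)
    types = sorted(set(truth.cell_types))
    genes: list[str] = []
    for t in types:
        genes += [f"{t}_mk{i}" for i in range(markers_per_type)]
    genes += [f"bg{i:03d}" for i in range(n_background_genes)]
    sig_genes = [f"sig{i:02d}" for i in range(n_signature_genes)]
    genes += sig_genes
    n_genes = len(genes)

    base_profiles = {}
    for t in types:
        prof = np.full(n_genes, base_level)
        for i in range(markers_per_type):
            prof[genes.index(f"{t}_mk{i}")] = marker_level
        base_profiles[t] = prof + rng.normal(0, 0.05, size=n_genes)

    patient_rng = np.random.default_rng(zlib.crc32(truth.patient.encode()) % 2**31)
    patient_shift = patient_rng.normal(0, patient_shift_sd, size=n_genes)

    loading = np.zeros(n_genes)
    for g in sig_genes:
        loading[genes.index(g)] = signature_effect

    malignant = truth.cell_types == "malignant"
    field_values = np.zeros(truth.n_cells)
    field_spec: dict = {"name": signature_field}
    if signature_field == "constant_high":
        field_values[malignant] = 1.0
    elif signature_field == "patched":
        lo = np.array([patch_radius, patch_radius])
        hi = np.array(truth.extent) - patch_radius
        centers = rng.uniform(lo, hi, size=(n_patches, 2))
        d = np.linalg.norm(truth.positions[:, None, :] - centers[None, :, :], axis=2)
        inside = (d <= patch_radius).any(axis=1)
        field_values[malignant & inside] = 1.0
        field_spec.update(
            {"centers": centers.tolist(), "radius": patch_radius, "n_patches": n_patches}
        )
    elif signature_field != "constant_low":
        raise ValueError(f"unknown signature field {signature_field!r}")

    truth.genes = genes
    truth.base_profiles = base_profiles
    truth.patient_shift = patient_shift
    truth.signature_genes = sig_genes
    truth.signature_loading = loading
    truth.signature_field = field_values
    truth.field_spec = field_spec
    return truth


def _poisson_counts(rng, lam: np.ndarray, nb_alpha: float) -> np.ndarray:
    if nb_alpha > 0:
        lam = rng.gamma(shape=1.0 / nb_alpha, scale=nb_alpha * lam)
    return rng.poisson(lam)


def _scatter_molecules(rng, counts, positions, genes, scatter_sd):
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    cell_idx = np.repeat(rows, reps)
    gene_idx = np.repeat(cols, reps)
    xy = positions[cell_idx] + rng.normal(0, scatter_sd, size=(len(cell_idx), 2))
    return pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "gene": np.asarray(genes)[gene_idx],
            "cell_id": cell_idx,
        }
    )


def _majority(series: pd.Series) -> str:
    return series.value_counts().idxmax()


def emulate_method(
    truth: GroundTruth, profile: MethodProfile, seed: int = 0
) -> tuple[SpatialDataset, MoleculeTable | None]:
    """Capture one section of the ground truth with one method's model.

    Returns the dataset plus the molecule table for molecule-resolved
    observation models (``bead``/``bin``), else ``None``.  Bead and bin
    observations carry the majority contributing cell type as their label.
    """
    rng = np.random.default_rng(seed)
    log_e = truth.expected_log_expression()
    panel = profile.panel if profile.panel is not None else list(truth.genes)
    panel_idx = [truth.genes.index(g) for g in panel]
    if not panel_idx:
        raise ValueError("empty panel intersection with simulated genes")
    lam = profile.efficiency * np.exp(log_e[:, panel_idx])

    base_meta = pd.DataFrame(
        {
            "cell_type": truth.cell_types,
            "patient": truth.patient,
            "sample": f"{truth.patient}_s0",
        }
    )

    if profile.observation_model == "intensity":
        intensity = profile.intensity_scale * lam + rng.normal(
            0, profile.intensity_noise_sd, size=lam.shape
        )
        ds = SpatialDataset(
            values=np.clip(intensity, 0, None),
            coords=truth.positions.copy(),
            method=profile.method,
            feature_names=list(panel),
            obs_meta=base_meta,
        )
        return ds, None

    counts = _poisson_counts(rng, lam, profile.nb_alpha)

    if profile.observation_model == "cell":
        ds = SpatialDataset(
            values=counts.astype(np.int64),
            coords=truth.positions.copy(),
            method=profile.method,
            feature_names=list(panel),
            obs_meta=base_meta,
        )
        return ds, None

    mol = _scatter_molecules(rng, counts, truth.positions, panel, profile.scatter_sd)
    mol_types = truth.cell_types[mol["cell_id"].to_numpy()]

    if profile.observation_model == "bin":
        b = profile.bin_size
    else:  # bead: keep only molecules inside a bead footprint
        b = profile.bead_spacing
        centers = (np.floor(mol[["x", "y"]].to_numpy() / b) + 0.5) * b
        dist = np.linalg.norm(mol[["x", "y"]].to_numpy() - centers, axis=1)
        keep = dist <= profile.bead_radius
        mol = mol.loc[keep].reset_index(drop=True)
        mol_types = mol_types[keep]
        if len(mol) == 0:
            raise ValueError("bead capture lost all molecules; lower scatter or raise counts")

    table = MoleculeTable(table=mol, panel=list(panel))
    from .core_data import bin_molecules

    ds = bin_molecules(table, b, method=profile.method)
    key = pd.MultiIndex.from_arrays(
        [
            np.floor(mol["x"].to_numpy() / b).astype(np.int64),
            np.floor(mol["y"].to_numpy() / b).astype(np.int64),
        ]
    )
    majority = pd.Series(mol_types, index=key).groupby(level=[0, 1]).agg(_majority)
    ds_key = pd.MultiIndex.from_arrays(
        [ds.obs_meta["bin_ix"].to_numpy(), ds.obs_meta["bin_iy"].to_numpy()]
    )
    ds.obs_meta["cell_type"] = majority.reindex(ds_key).to_numpy()
    ds.obs_meta["patient"] = truth.patient
    ds.obs_meta["sample"] = f"{truth.patient}_s0"
    return ds, table


def emulate_serial_sections(
    truth: GroundTruth,
    profiles: list[MethodProfile],
    perturb_rotation_sd: float = 5.0,
    perturb_shift_sd: float = 50.0,
    jitter_sd: float = 0.5,
    seed: int = 0,
) -> list[dict]:
    """Emulate serial sections: one capture per profile, each rigidly perturbed.

    Every section is an independent capture of the same truth with a small
    positional jitter and a random rigid perturbation (rotation
    N(0, ``perturb_rotation_sd`` deg), translation N(0, ``perturb_shift_sd``)
    um about the tissue center).  The inverse transform of each perturbation
    is recorded so registration can be tested against ground truth.

    Returns one record per section: ``{"dataset", "molecules", "transform",
    "inverse", "truth_seed"}``.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one section profile")
    rng = np.random.default_rng(seed)
    center = (truth.extent[0] / 2, truth.extent[1] / 2)
    sections = []
    for k, profile in enumerate(profiles):
        ds, mol = emulate_method(truth, profile, seed=int(rng.integers(2**31)))
        ds.coords = ds.coords + rng.normal(0, jitter_sd, size=ds.coords.shape)
        t = RigidTransform(
            rotation_deg=float(rng.normal(0, perturb_rotation_sd)),
            dx=float(rng.normal(0, perturb_shift_sd)),
            dy=float(rng.normal(0, perturb_shift_sd)),
            pivot=center,
        )
        ds.coords = t.apply(ds.coords)
        ds.obs_meta["replicate"] = f"r{k}"
        ds.attrs["truth_seed"] = truth.seed
        sections.append(
            {
                "dataset": ds,
                "molecules": mol,
                "transform": t,
                "inverse": t.invert(),
                "truth_seed": truth.seed,
            }
        )
    return sections
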