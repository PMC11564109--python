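"""Common observation x feature data model and spatial harmonization.

All spatial assays (segmented cells, capture beads, square bins, intensity
imaging) are represented in one container, :class:`SpatialDataset`, holding an
observation x feature matrix, per-observation (x, y) coordinates in micrometers
and per-observation metadata.  Harmonization consists of molecule binning,
coordinate rescaling to 1 um per unit, rigid registration of serial sections
against a reference frame, and clipping/annotation against a tissue mask.

Coordinate conventions (fixed across the package):

* continuous um, y increasing upward, section origin at the coordinate minimum;
* bin lattices anchored at (0, 0) with half-open intervals ``[k*b, (k+1)*b)``;
* rigid transforms apply in the order flip -> scale -> rotate -> translate,
  all about a stated pivot;
* polygon clipping uses a closed boundary (points on the edge are kept).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix
from shapely.geometry import shape as _geojson_shape

__all__ = [
    "METHODS",
    "INTENSITY_METHODS",
    "SpatialDataset",
    "MoleculeTable",
    "RigidTransform",
    "SectionMask",
    "bin_molecules",
    "rescale_coordinates",
    "apply_transform",
    "register_sections",
    "clip_and_annotate",
    "read_molecule_csv",
    "write_molecule_csv",
    "read_dataset",
    "write_dataset",
    "load_registration_config",
    "read_section_mask",
    "write_section_mask",
]

#: Recognized method tags.  ``codex`` is the only intensity-mode method; all
#: others carry nonnegative integer counts.
METHODS = frozenset(
    {"sc", "sn", "slideseq", "merfish_cell", "merfish_bin", "exseq_cell", "exseq_bin", "codex"}
)
INTENSITY_METHODS = frozenset({"codex"})


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty molecule table or dataset."""


@dataclass
class SpatialDataset:
    """Observation x feature matrix with um coordinates and metadata.

    Parameters
    ----------
    values
        ``(n_obs, n_features)`` array; nonnegative integers for count-mode
        methods, nonnegative reals for intensity-mode methods.
    coords
        ``(n_obs, 2)`` array of (x, y) positions in um.
    method
        One of :data:`METHODS`.
    feature_names
        Unique gene/protein identifiers (official gene alias for all methods).
    obs_meta
        Per-observation records (sample/patient/replicate ids, categorical
        cell type, region label, ...), indexed like the rows of ``values``.
    """

    values: np.ndarray
    coords: np.ndarray
    method: str
    feature_names: list[str]
    obs_meta: pd.DataFrame | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n_obs, 2)")
        if self.values.shape[0] != self.coords.shape[0]:
            raise ValueError("values and coords disagree on n_obs")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match values columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if self.obs_meta is None:
            self.obs_meta = pd.DataFrame(index=pd.RangeIndex(self.n_obs))
        if len(self.obs_meta) != self.n_obs:
            raise ValueError("obs_meta length must match n_obs")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_count_mode(self) -> bool:
        return self.method not in INTENSITY_METHODS

    def validate(self) -> None:
        """Check container invariants; raise ``ValueError`` on violation."""
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("values must be nonnegative")
        if self.is_count_mode:
            v = np.asarray(self.values)
            if not np.allclose(v, np.round(v)):
                raise ValueError("count-mode values must be integers")
        comp_cols = [c for c in self.obs_meta.columns if c.startswith("comp_")]
        if comp_cols:
            comp = self.obs_meta[comp_cols].to_numpy(dtype=float)
            if np.any(comp < 0) or not np.allclose(comp.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("compositional vectors must be >=0 and sum to 1")

    def copy(self) -> "SpatialDataset":
        return SpatialDataset(
            values=self.values.copy(),
            coords=self.coords.copy(),
            method=self.method,
            feature_names=list(self.feature_names),
            obs_meta=self.obs_meta.copy(),
            attrs=dict(self.attrs),
        )

    def to_anndata(self):
        """Export as :class:`anndata.AnnData` with coordinates in obsm['spatial']."""
        import anndata

        ad = anndata.AnnData(
            X=np.asarray(self.values, dtype=float),
            obs=self.obs_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.feature_names, name="feature")),
        )
        ad.obsm["spatial"] = self.coords.copy()
        ad.uns["method"] = self.method
        return ad


@dataclass
class MoleculeTable:
    """Single-molecule records (x um, y um, feature name[, cell id])."""

    table: pd.DataFrame
    panel: list[str] | None = None

    def __post_init__(self) -> None:
        required = {"x", "y", "gene"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"molecule table missing columns {sorted(missing)}")
        xy = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("molecule coordinates must be finite")
        if self.panel is not None:
            unknown = ~self.table["gene"].isin(self.panel)
            if unknown.any():
                rows = self.table.index[unknown].tolist()[:20]
                raise ValueError(
                    f"molecule table contains genes outside the declared panel "
                    f"(offending rows {rows})"
                )

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body transform: flip -> scale -> rotate -> translate about a pivot.

    The forward map is ``q = pivot + R(theta) * s * F * (c - pivot) + (dx, dy)``
    where ``F`` flips the x and/or y axis.  Rotation is counter-clockwise in
    degrees.  ``scale`` must be positive.
    """

    rotation_deg: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    flip_h: bool = False
    flip_v: bool = False
    scale: float = 1.0
    pivot: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def _matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        flip = np.diag([-1.0 if self.flip_h else 1.0, -1.0 if self.flip_v else 1.0])
        return rot @ (self.scale * flip)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        pivot = np.asarray(self.pivot, dtype=float)
        return (coords - pivot) @ self._matrix().T + pivot + np.array([self.dx, self.dy])

    def invert(self) -> "RigidTransform":
        """Analytic inverse, expressed in the same parameterization.

        Uses ``F R(a) F = R(-a)`` for a single-axis flip (a double flip is a
        180-degree rotation and commutes).
        """
        single_flip = self.flip_h != self.flip_v
        theta_inv = self.rotation_deg if single_flip else -self.rotation_deg
        minv = np.linalg.inv(self._matrix())
        t_inv = -minv @ np.array([self.dx, self.dy])
        return RigidTransform(
            rotation_deg=theta_inv,
            dx=float(t_inv[0]),
            dy=float(t_inv[1]),
            flip_h=self.flip_h,
            flip_v=self.flip_v,
            scale=1.0 / self.scale,
            pivot=self.pivot,
        )

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg,
            "dx": self.dx,
            "dy": self.dy,
            "flip_h": self.flip_h,
            "flip_v": self.flip_v,
            "scale": self.scale,
            "pivot": list(self.pivot),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=float(d.get("rotation_deg", 0.0)),
            dx=float(d.get("dx", 0.0)),
            dy=float(d.get("dy", 0.0)),
            flip_h=bool(d.get("flip_h", False)),
            flip_v=bool(d.get("flip_v", False)),
            scale=float(d.get("scale", 1.0)),
            pivot=tuple(d.get("pivot", (0.0, 0.0))),
        )


@dataclass
class SectionMask:
    """Tissue polygons in um, optionally labeled with sub-region names."""

    polygons: list
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = [f"region_{i}" for i in range(len(self.polygons))]
        if len(self.labels) != len(self.polygons):
            raise ValueError("one label per polygon required")
        for poly in self.polygons:
            if not poly.is_valid:
                raise ValueError("mask polygons must be simple (non-self-intersecting)")
        if self.total_area() <= 0:
            raise ValueError("mask must have positive area")

    def total_area(self) -> float:
        return float(sum(p.area for p in self.polygons))


# ---------------------------------------------------------------------------
# operations


def bin_molecules(
    molecules: MoleculeTable, bin_size: float, method: str = "merfish_bin"
) -> SpatialDataset:
    """Aggregate a molecule table onto a square-bin lattice.

    Bins live on a lattice anchored at the origin with half-open intervals
    ``[k*b, (k+1)*b)``; each molecule falls in exactly one bin.  Returned
    coordinates are bin centers; empty bins are omitted; total counts are
    conserved.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if len(molecules) == 0:
        raise EmptyInputError("cannot bin an empty molecule table")
    tab = molecules.table
    ix = np.floor(tab["x"].to_numpy(dtype=float) / bin_size).astype(np.int64)
    iy = np.floor(tab["y"].to_numpy(dtype=float) / bin_size).astype(np.int64)
    genes = tab["gene"].to_numpy()
    feature_names = sorted(set(molecules.panel)) if molecules.panel else sorted(set(genes))
    gene_idx = pd.Series(np.arange(len(feature_names)), index=feature_names)
    df = pd.DataFrame({"ix": ix, "iy": iy, "g": gene_idx[genes].to_numpy()})
    grouped = df.groupby(["ix", "iy", "g"]).size()
    bins = grouped.index.droplevel("g").unique()
    bin_idx = pd.Series(np.arange(len(bins)), index=bins)
    rows = bin_idx[grouped.index.droplevel("g")].to_numpy()
    cols = grouped.index.get_level_values("g").to_numpy()
    mat = np.zeros((len(bins), len(feature_names)), dtype=np.int64)
    np.add.at(mat, (rows, cols), grouped.to_numpy())
    centers = np.array([[(bx + 0.5) * bin_size, (by + 0.5) * bin_size] for bx, by in bins])
    meta = pd.DataFrame({"bin_ix": [b[0] for b in bins], "bin_iy": [b[1] for b in bins]})
    return SpatialDataset(
        values=mat,
        coords=centers,
        method=method,
        feature_names=feature_names,
        obs_meta=meta,
        attrs={"bin_size": bin_size},
    )


def rescale_coordinates(dataset: SpatialDataset, native_resolution: float) -> SpatialDataset:
    """Convert pixel coordinates to um and shift the section origin to (0, 0).

    Coordinates are multiplied by ``native_resolution`` (um per pixel) and
    translated so each axis starts at zero.  Values are untouched.
    """
    if native_resolution <= 0:
        raise ValueError("native_resolution must be > 0")
    out = dataset.copy()
    out.coords = out.coords * native_resolution
    out.coords = out.coords - out.coords.min(axis=0)
    return out


def apply_transform(dataset: SpatialDataset, t: RigidTransform) -> SpatialDataset:
    """Apply a rigid transform to dataset coordinates (values untouched)."""
    out = dataset.copy()
    out.coords = t.apply(out.coords)
    return out


def register_sections(
    moving: SpatialDataset,
    key: tuple[str, str, str] | str,
    config: dict,
    reference_mask: SectionMask | None = None,
) -> SpatialDataset:
    """Register a section into the reference frame using a declarative config.

    ``config`` maps ``"sample/method/replicate"`` keys (or nested dicts) to
    transform parameter dicts; the transform actually used is recorded in
    ``attrs['registration']`` for reproducibility.
    """
    if isinstance(key, tuple):
        key = "/".join(key)
    if key not in config:
        raise KeyError(f"no registration transform recorded for section {key!r}")
    t = RigidTransform.from_dict(config[key])
    out = apply_transform(moving, t)
    out.attrs["registration"] = {"key": key, **t.to_dict()}
    if reference_mask is not None:
        out.attrs["reference_mask_area"] = reference_mask.total_area()
    return out


def clip_and_annotate(dataset: SpatialDataset, mask: SectionMask) -> SpatialDataset:
    """Drop observations outside the mask; annotate the rest by sub-region.

    Containment uses a closed boundary: points exactly on a polygon edge are
    retained.  When sub-regions overlap, the first containing polygon (in mask
    order) wins.
    """
    if mask.total_area() <= 0:
        raise ValueError("mask must have positive area")
    x, y = dataset.coords[:, 0], dataset.coords[:, 1]
    points = shapely.points(x, y)
    region = np.full(dataset.n_obs, None, dtype=object)
    inside = np.zeros(dataset.n_obs, dtype=bool)
    for poly, label in zip(mask.polygons, mask.labels):
        cov = shapely.covers(poly, points)
        new = cov & ~inside
        region[new] = label
        inside |= cov
    out = dataset.copy()
    out.values = out.values[inside]
    out.coords = out.coords[inside]
    out.obs_meta = out.obs_meta.loc[inside].reset_index(drop=True)
    out.obs_meta["region"] = region[inside]
    return out


# ---------------------------------------------------------------------------
# I/O: molecule CSV, MTX + TSV sidecars, YAML registration config, GeoJSON masks


def read_molecule_csv(path, panel: list[str] | None = None) -> MoleculeTable:
    tab = pd.read_csv(path)
    return MoleculeTable(table=tab, panel=panel)


def write_molecule_csv(molecules: MoleculeTable, path) -> None:
    cols = ["x", "y", "gene"] + (["cell_id"] if "cell_id" in molecules.table else [])
    molecules.table[cols].to_csv(path, index=False)


_OBS_COLUMNS = ["x", "y"]


def write_dataset(dataset: SpatialDataset, outdir) -> None:
    """Write a dataset as Matrix Market values plus TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = coo_matrix(np.asarray(dataset.values, dtype=float))
    mmwrite(outdir / "matrix.mtx", sparse)
    obs = dataset.obs_meta.copy()
    obs.insert(0, "y", dataset.coords[:, 1])
    obs.insert(0, "x", dataset.coords[:, 0])
    obs.insert(0, "obs_id", [f"obs{i}" for i in range(dataset.n_obs)])
    obs.to_csv(outdir / "obs.tsv", sep="\t", index=False)
    pd.Series(dataset.feature_names, name="feature").to_csv(
        outdir / "features.tsv", sep="\t", index=False
    )
    (outdir / "dataset.json").write_text(
        json.dumps({"method": dataset.method, "attrs": _jsonable(dataset.attrs)})
    )


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        try:
            json.dumps(v)
            out[k] = v
        except TypeError:
            out[k] = str(v)
    return out


def read_dataset(outdir) -> SpatialDataset:
    outdir = Path(outdir)
    values = np.asarray(mmread(outdir / "matrix.mtx").todense())
    obs = pd.read_csv(outdir / "obs.tsv", sep="\t")
    if obs["obs_id"].duplicated().any():
        raise ValueError("duplicate observation ids")
    features = pd.read_csv(outdir / "features.tsv", sep="\t")["feature"].tolist()
    meta = json.loads((outdir / "dataset.json").read_text())
    coords = obs[["x", "y"]].to_numpy(dtype=float)
    obs_meta = obs.drop(columns=["obs_id", "x", "y"])
    method = meta["method"]
    if method not in INTENSITY_METHODS:
        values = np.round(values).astype(np.int64)
    return SpatialDataset(
        values=values,
        coords=coords,
        method=method,
        feature_names=features,
        obs_meta=obs_meta,
        attrs=meta.get("attrs", {}),
    )


def load_registration_config(path) -> dict:
    """Load a YAML registration config keyed by ``sample/method/replicate``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("registration config must be a mapping")
    return cfg


def read_section_mask(path) -> SectionMask:
    """Read a GeoJSON FeatureCollection of polygons (um coordinates)."""
    gj = json.loads(Path(path).read_text())
    polygons, labels = [], []
    for i, feat in enumerate(gj["features"]):
        polygons.append(_geojson_shape(feat["geometry"]))
        labels.append(feat.get("properties", {}).get("label", f"region_{i}"))
    return SectionMask(polygons=polygons, labels=labels)


def write_section_mask(mask: SectionMask, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"label": label},
            "geometry": json.loads(shapely.to_geojson(poly)),
        }
        for poly, label in zip(mask.polygons, mask.labels)
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
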