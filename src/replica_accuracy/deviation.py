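"""Per-vertex surface deviation fields and their summaries.

Two metrics are computed between registered surface models:

* the *Euclidean distance* — the unsigned distance from each vertex of the
  basis mesh to the closest point anywhere on the other surface;
* the *normal distance* — the directed distance from each vertex along its
  outward surface normal to the nearest intersection with the other
  surface. Its sign encodes which model is locally larger; in every report
  of this package, positive means the natural tooth is larger than the
  compared model.

The Euclidean distance lower-bounds the magnitude of the normal distance
(the closest point cannot be farther than any particular ray hit), and it
absorbs tangential registration slack that the normal metric largely
ignores. Vertices whose normal ray meets nothing within ``max_range`` are
flagged missing and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, SurfaceMesh
from .registration import ICPConfig, ICPResult, icp_register

__all__ = [
    "DistanceField",
    "SummaryStats",
    "ComparisonResult",
    "euclidean_field",
    "normal_field",
    "summarize",
    "compare_models",
]


@dataclass
class DistanceField:
    """Per-vertex deviations (mm) on a basis mesh.

    ``metric`` is ``"euclidean"`` (non-negative) or ``"normal"`` (signed).
    ``missing`` flags vertices without a valid value (no ray intersection).
    """

    basis_mesh_id: str
    values: np.ndarray
    metric: str
    missing: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.metric not in ("euclidean", "normal"):
            raise ValueError("metric must be 'euclidean' or 'normal'")
        if self.missing is None:
            self.missing = np.zeros(len(self.values), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool).ravel()
        if len(self.missing) != len(self.values):
            raise ValueError("missing flags must match values length")
        if self.metric == "euclidean" and np.nanmin(
            np.where(self.missing, 0.0, self.values)
        ) < 0:
            raise ValueError("euclidean field cannot be negative")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.missing]

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


@dataclass(frozen=True)
class SummaryStats:
    """Order statistics and moments of a deviation distribution (mm)."""

    min: float
    max: float
    mean: float
    median: float
    n_valid: int
    n_missing: int
    abs_mean: float | None = None
    abs_median: float | None = None

    def as_dict(self) -> dict:
        out = {
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
            "median": self.median,
            "n_valid": self.n_valid,
            "n_missing": self.n_missing,
        }
        if self.abs_mean is not None:
            out["abs_mean"] = self.abs_mean
            out["abs_median"] = self.abs_median
        return out


def euclidean_field(
    basis: SurfaceMesh, other: SurfaceMesh, basis_mesh_id: str = "basis"
) -> DistanceField:
    """Unsigned distance from every basis vertex to the closest point on
    ``other`` (exact point-to-triangle). Never has missing values."""
    if basis.n_faces == 0 or other.n_faces == 0:
        raise GeometryError("empty mesh")
    d = other.query().distances(basis.vertices)
    return DistanceField(basis_mesh_id, d, "euclidean")


def normal_field(
    basis: SurfaceMesh,
    other: SurfaceMesh,
    max_range: float = 5.0,
    basis_mesh_id: str = "basis",
    flip_sign: bool = False,
) -> DistanceField:
    """Signed distance from each basis vertex along its outward normal.

    Both ray directions are cast and the nearest hit within ``max_range``
    wins; the raw sign is positive when ``other`` lies on the outward side
    of the basis surface. ``flip_sign`` inverts the convention (used when
    the basis mesh is the reference model rather than the compared one, so
    that *positive always means the natural tooth is locally larger*).
    Vertices with no hit are flagged missing.
    """
    if basis.n_faces == 0 or other.n_faces == 0:
        raise GeometryError("empty mesh")
    if not basis.is_closed() or basis.volume <= 0:
        raise GeometryError(
            "basis mesh must be closed and outward-oriented for normal "
            "distances; re-orient (flip faces) or repair the mesh first"
        )
    normals = basis.vertex_normals()
    t, hit = other.query().line_intersections(basis.vertices, normals, max_range)
    values = np.where(hit, t, 0.0)
    if flip_sign:
        values = -values
    return DistanceField(basis_mesh_id, values, "normal", missing=~hit)


def summarize(field: DistanceField) -> SummaryStats:
    """Min / max / mean / median over valid values; absolute-value variants
    are populated for signed fields. Even counts use the midpoint median."""
    v = field.valid_values
    if len(v) == 0:
        raise ValueError("cannot summarize an all-missing field")
    stats = dict(
        min=float(v.min()),
        max=float(v.max()),
        mean=float(v.mean()),
        median=float(np.median(v)),
        n_valid=int(len(v)),
        n_missing=field.n_missing,
    )
    if field.metric == "normal":
        a = np.abs(v)
        stats["abs_mean"] = float(a.mean())
        stats["abs_median"] = float(np.median(a))
    return SummaryStats(**stats)


@dataclass
class ComparisonResult:
    """Output of one model-vs-natural comparison."""

    basis: str  # "model" or "natural"
    registration: ICPResult
    registered_model: SurfaceMesh
    euclidean: DistanceField
    normal: DistanceField
    euclidean_stats: SummaryStats
    normal_stats: SummaryStats
    basis_mesh: SurfaceMesh = None


def compare_models(
    natural_scan: SurfaceMesh,
    model: SurfaceMesh,
    basis_choice: str = "model",
    icp_cfg: ICPConfig | None = None,
    max_range: float = 5.0,
) -> ComparisonResult:
    """Register ``model`` onto ``natural_scan`` and compute both deviation
    fields with summaries.

    ``basis_choice`` selects the mesh whose vertices carry the fields: the
    reconstruction/replica model (values drawn on the model, the
    convention for CBCT-model comparisons) or the natural scan (the
    convention for replica comparisons). The sign of the normal field is
    arranged so positive always means the natural tooth is locally larger.
    """
    if basis_choice not in ("model", "natural"):
        raise ValueError("basis_choice must be 'model' or 'natural'")
    reg = icp_register(model, natural_scan, icp_cfg)
    moved = reg.transform.apply_mesh(model)
    if basis_choice == "model":
        basis, other, flip = moved, natural_scan, False
    else:
        basis, other, flip = natural_scan, moved, True
    eu = euclidean_field(basis, other, basis_mesh_id=basis_choice)
    nm = normal_field(
        basis, other, max_range=max_range, basis_mesh_id=basis_choice,
        flip_sign=flip,
    )
    return ComparisonResult(
        basis=basis_choice,
        registration=reg,
        registered_model=moved,
        euclidean=eu,
        normal=nm,
        euclidean_stats=summarize(eu),
        normal_stats=summarize(nm),
        basis_mesh=basis,
    )
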