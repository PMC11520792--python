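"""Summary tables and color-mapped deviation renderings.

Deviation fields are visualized with a linear two-point RGB ramp from dark
blue (#00008B) to bright yellow (#FFFF00): dark blue marks the minimum
(most negative, for signed fields) value and bright yellow the maximum
(most positive). For signed fields this means bright yellow regions are
where the natural tooth is locally larger than the compared model.
Missing vertices render neutral gray. Tables report min / mean / median /
max (plus absolute mean and median for signed metrics) in mm with three
significant figures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deviation import DistanceField, SummaryStats
from .geometry import SurfaceMesh

__all__ = [
    "ComparisonReport",
    "colormap_mesh",
    "colormap_values",
    "build_report",
    "write_report_csv",
    "read_report_csv",
    "write_colored_ply",
    "render_deviation_png",
]

RAMP_BLUE = np.array([0x00, 0x00, 0x8B], dtype=np.float64) / 255.0
RAMP_YELLOW = np.array([0xFF, 0xFF, 0x00], dtype=np.float64) / 255.0
MISSING_GRAY = np.array([0.5, 0.5, 0.5])


@dataclass
class ComparisonReport:
    """One row-group of the study report: a tooth, a comparison arm, and
    the summary statistics of both metrics."""

    tooth_label: str
    comparison: str  # "cbct_vs_natural" | "replica_vs_natural"
    euclidean_stats: SummaryStats
    normal_stats: SummaryStats
    field_file_paths: str = ""

    def __post_init__(self):
        if self.comparison not in ("cbct_vs_natural", "replica_vs_natural"):
            raise ValueError("unknown comparison arm")
        for s in (self.euclidean_stats, self.normal_stats):
            if not (s.min <= s.median <= s.max):
                raise ValueError("inconsistent summary statistics")


def colormap_values(
    values: np.ndarray, missing: np.ndarray | None = None
) -> np.ndarray:
    """Map values linearly onto the blue-to-yellow ramp; (n, 3) floats.

    The minimum maps exactly to the blue endpoint and the maximum to the
    yellow endpoint; a constant field maps to the mid-ramp color. Missing
    entries map to neutral gray.
    """
    v = np.asarray(values, dtype=np.float64)
    if missing is None:
        missing = np.zeros(len(v), dtype=bool)
    valid = ~missing
    out = np.tile(MISSING_GRAY, (len(v), 1))
    if valid.any():
        lo, hi = v[valid].min(), v[valid].max()
        t = np.full(len(v), 0.5) if hi == lo else (v - lo) / (hi - lo)
        out[valid] = (
            RAMP_BLUE + t[valid, None] * (RAMP_YELLOW - RAMP_BLUE)
        )
    return out


def colormap_mesh(
    mesh: SurfaceMesh, field: DistanceField, mode: str = "magnitude"
):
    """Per-vertex ramp colors for a deviation field on its basis mesh.

    ``magnitude`` maps [min, max] of the raw values; ``signed`` is the same
    linear map but asserts a signed field (most negative -> dark blue, most
    positive -> bright yellow). Returns (n, 3) float colors in [0, 1].
    """
    if mode not in ("magnitude", "signed"):
        raise ValueError("mode must be 'magnitude' or 'signed'")
    if mode == "signed" and field.metric != "normal":
        raise ValueError("signed mode requires a signed (normal) field")
    if len(field.values) != mesh.n_vertices:
        raise ValueError("field basis does not match mesh")
    return colormap_values(field.values, field.missing)


def write_colored_ply(
    path, mesh: SurfaceMesh, colors: np.ndarray
) -> None:
    """ASCII PLY with per-vertex RGB."""
    rgb = np.clip(np.round(np.asarray(colors) * 255), 0, 255).astype(np.uint8)
    if len(rgb) != mesh.n_vertices:
        raise ValueError("one color per vertex required")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write(
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        )
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, c in zip(mesh.vertices, rgb):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {c[0]} {c[1]} {c[2]}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def render_deviation_png(
    path, mesh: SurfaceMesh, field: DistanceField, mode: str = "magnitude",
    max_faces: int = 20000,
) -> None:
    """Static 3-D rendering of a colored deviation field (matplotlib).

    Large meshes are decimated by uniform face subsampling purely for
    display speed; the data products (CSV/PLY) always carry every vertex.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from mpl_toolkits.mplot3d.art3d import Poly3DCollection

    colors = colormap_mesh(mesh, field, mode)
    faces = mesh.faces
    if len(faces) > max_faces:
        step = int(np.ceil(len(faces) / max_faces))
        faces = faces[::step]
    tri = mesh.vertices[faces]
    face_col = colors[faces].mean(axis=1)
    fig = plt.figure(figsize=(5, 7))
    ax = fig.add_subplot(projection="3d")
    pc = Poly3DCollection(tri, facecolors=face_col, edgecolors="none")
    ax.add_collection3d(pc)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    c = (lo + hi) / 2
    r = (hi - lo).max() / 2
    ax.set_xlim(c[0] - r, c[0] + r)
    ax.set_ylim(c[1] - r, c[1] + r)
    ax.set_zlim(c[2] - r, c[2] + r)
    ax.set_box_aspect((1, 1, 1))
    ax.set_axis_off()
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def format_sig(x: float, sig: int = 3) -> str:
    """Significant-figure formatting in plain decimal notation, keeping
    trailing zeros (0.003 -> '0.00300', 0.928 -> '0.928', 2.345 -> '2.35')."""
    if x == 0 or not np.isfinite(x):
        return "0.00" if x == 0 else str(x)
    exponent = int(np.floor(np.log10(abs(x))))
    decimals = max(sig - 1 - exponent, 0)
    s = f"{x:.{decimals}f}"
    # rounding may carry over a digit (0.0999 -> 0.100 at 3 sig figs)
    if float(s) != 0 and abs(float(s)) >= 10 ** (exponent + 1):
        decimals = max(decimals - 1, 0)
        s = f"{x:.{decimals}f}"
    return s


_COLUMNS = [
    "tooth", "comparison", "metric",
    "min_mm", "mean_mm", "median_mm", "max_mm",
    "abs_mean_mm", "abs_median_mm", "n_valid", "n_missing",
]


def build_report(reports: list) -> pd.DataFrame:
    """One row per (tooth, comparison, metric) with the summary columns.

    Signed (normal) rows carry absolute mean/median as well; euclidean rows
    leave those columns empty. The frame is a pure function of its inputs.
    """
    if not reports:
        raise ValueError("at least one report required")
    rows = []
    for r in reports:
        for metric, s in (
            ("euclidean", r.euclidean_stats),
            ("normal", r.normal_stats),
        ):
            rows.append(
                {
                    "tooth": r.tooth_label,
                    "comparison": r.comparison,
                    "metric": metric,
                    "min_mm": s.min,
                    "mean_mm": s.mean,
                    "median_mm": s.median,
                    "max_mm": s.max,
                    "abs_mean_mm": s.abs_mean,
                    "abs_median_mm": s.abs_median,
                    "n_valid": s.n_valid,
                    "n_missing": s.n_missing,
                }
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_report_csv(path, frame: pd.DataFrame, header_lines=()) -> None:
    """Write the report with values at 3 significant figures. Run metadata
    goes into comment lines above the table, never into data rows."""
    out = frame.copy()
    for col in ("min_mm", "mean_mm", "median_mm", "max_mm",
                "abs_mean_mm", "abs_median_mm"):
        out[col] = [
            "" if v is None or (isinstance(v, float) and np.isnan(v))
            else format_sig(v)
            for v in out[col]
        ]
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    out.to_csv(buf, index=False)
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def read_report_csv(path) -> pd.DataFrame:
    """Parse a report written by :func:`write_report_csv`."""
    return pd.read_csv(path, comment="#")
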