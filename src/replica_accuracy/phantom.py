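"""Synthetic tooth phantoms with known ground truth.

The study design this package reproduces needs three inputs per tooth: an
optical-scan-quality reference surface, a CBCT-like voxel volume, and a
replica surface with fabrication noise. Real teeth are not available, so a
parametric phantom stands in: the crown is a superellipsoid and each root a
sphere-swept tapered cone, blended with a smooth union so that multi-rooted
phantoms exhibit a furcation saddle. The implicit field is polygonized by
marching cubes at a pitch finer than the CBCT voxel, giving a closed,
outward-oriented ground-truth mesh.

All phantom operations are pure functions of their arguments (including the
seed), so identical inputs regenerate bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from skimage import measure

from .geometry import GeometryError, SurfaceMesh, voxelize_solid

__all__ = [
    "PhantomSpec",
    "RootSpec",
    "VoxelVolume",
    "TOOTH_KINDS",
    "make_phantom",
    "voxelize",
    "deform_bump",
    "simulate_replica",
    "canal_segments",
    "deformity_site",
]

TOOTH_KINDS = ("premolar", "canine", "molar")

#: HU threshold that segmentation uses downstream; voxelize() enforces that
#: hard tissue and background straddle it so the phantom is segmentable.
SEGMENTATION_THRESHOLD_HU = 1600.0


@dataclass(frozen=True)
class RootSpec:
    """One root: base attachment point, length and taper radii (mm)."""

    apex_offset: tuple  # base attachment point, mm, relative to crown center
    length: float
    base_radius: float
    tip_radius: float

    def __post_init__(self):
        if self.length <= 0 or self.base_radius <= 0 or self.tip_radius <= 0:
            raise ValueError("root dimensions must be strictly positive")
        if self.tip_radius >= self.base_radius:
            raise ValueError("tip_radius must be smaller than base_radius")

    @property
    def axis(self) -> np.ndarray:
        """Unit direction of the root, tilting outward with lateral offset."""
        a = np.asarray(self.apex_offset, dtype=np.float64)
        d = np.array([0.18 * a[0], 0.18 * a[1], -1.0])
        return d / np.linalg.norm(d)

    @property
    def base_point(self) -> np.ndarray:
        return np.asarray(self.apex_offset, dtype=np.float64)

    @property
    def tip_point(self) -> np.ndarray:
        return self.base_point + self.length * self.axis


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic tooth; ground truth for tests."""

    tooth_kind: str
    crown_half_axes: tuple  # (a, b, c) mm
    root_specs: tuple  # tuple of RootSpec
    canal_radius: tuple  # mm, one per root
    seed: int

    def __post_init__(self):
        if self.tooth_kind not in TOOTH_KINDS:
            raise ValueError(f"unknown tooth_kind {self.tooth_kind!r}")
        n_roots = len(self.root_specs)
        if self.tooth_kind in ("premolar", "canine") and n_roots != 1:
            raise ValueError(f"{self.tooth_kind} must have exactly 1 root")
        if self.tooth_kind == "molar" and n_roots < 2:
            raise ValueError("molar must have >= 2 roots (furcation)")
        if len(self.canal_radius) != n_roots:
            raise ValueError("one canal radius per root required")
        if any(x <= 0 for x in self.crown_half_axes):
            raise ValueError("crown half-axes must be strictly positive")
        if any(r <= 0 for r in self.canal_radius):
            raise ValueError("canal radii must be strictly positive")


# Fixed shape parameters per kind; the seed never alters the geometry, it
# only feeds stochastic operations downstream (noise, milling). Roots are
# deliberately tilted and, for the molar, unequal: natural teeth have no
# rotational symmetry, and a registration problem against a near-surface-of-
# revolution would be ill-posed about that axis.
_KIND_PARAMS = {
    "premolar": dict(
        crown=(3.6, 3.0, 4.2),
        roots=(RootSpec((0.6, 0.3, -2.0), 13.0, 2.4, 0.5),),
        canal=(0.5,),
    ),
    "canine": dict(
        crown=(3.3, 2.8, 4.8),
        roots=(RootSpec((0.5, -0.4, -2.2), 16.0, 2.6, 0.55),),
        canal=(0.5,),
    ),
    "molar": dict(
        crown=(5.2, 4.5, 3.8),
        roots=(
            RootSpec((-2.4, 0.3, -1.6), 11.0, 2.1, 0.5),
            RootSpec((2.4, -0.2, -1.6), 9.5, 1.8, 0.45),
        ),
        canal=(0.45, 0.4),
    ),
}

_CROWN_EXPONENT = 2.5
_BLEND_K = 0.8  # mm, smooth-union blending width at the cervical junction

# Angular crown modulation (cusp lobes) and mesiodistal root compression.
# Besides realism, these remove the near-rotational symmetry of a smooth
# crown + round root, which would leave rigid registration ill-conditioned
# about the long axis (real teeth pose no such ambiguity).
_CUSP_PATTERN = {
    "premolar": ((2, 0.10),),  # two cusps
    "canine": ((1, 0.13), (3, 0.06)),  # dominant labial ridge + cingulum
    "molar": ((4, 0.08), (1, 0.03)),  # four cusps, mesial/distal asymmetry
}
# Single roots are markedly oval (compressed mesiodistally); the molar's
# registration is already fully constrained by its two unequal roots, and
# its root cross-sections are closer to round.
_ROOT_Y_SCALE = {"premolar": 0.78, "canine": 0.78, "molar": 1.0}


@dataclass
class VoxelVolume:
    """3-D scalar grid of Hounsfield-like values with physical geometry.

    Axis order is (x, y, z); ``origin`` is the physical position of the
    center of voxel (0, 0, 0).
    """

    values: np.ndarray  # (nx, ny, nz) float64, HU
    spacing: np.ndarray  # (3,) mm/voxel
    origin: np.ndarray  # (3,) mm

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("volume must be 3-D with >= 2 voxels per axis")
        if (self.spacing <= 0).any():
            raise ValueError("spacing components must be positive")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


# ---------------------------------------------------------------------------
# implicit field
# ---------------------------------------------------------------------------


def _sd_superellipsoid(p: np.ndarray, half_axes, cusps=()) -> np.ndarray:
    """Pseudo signed distance of a superellipsoid crown (negative inside),
    optionally with angular lobes emulating cusps/ridges."""
    q = p / np.asarray(half_axes)
    if cusps:
        phi = np.arctan2(q[..., 1], q[..., 0])
        scale = np.ones_like(phi)
        for k, m in cusps:
            scale = scale + m * np.cos(k * phi)
        q = q.copy()
        q[..., 0] = q[..., 0] / scale
        q[..., 1] = q[..., 1] / scale
    r = (np.abs(q) ** _CROWN_EXPONENT).sum(axis=-1) ** (1.0 / _CROWN_EXPONENT)
    return (r - 1.0) * float(min(half_axes))


def _sd_round_cone(p, a, b, r1, r2):
    """Exact signed distance of a sphere-swept cone from a (r1) to b (r2)."""
    ba = b - a
    l2 = float(ba @ ba)
    rr = r1 - r2
    a2 = l2 - rr * rr
    il2 = 1.0 / l2
    pa = p - a
    y = pa @ ba
    z = y - l2
    x2 = ((pa * l2 - np.outer(y, ba)) ** 2).sum(axis=-1)
    y2 = y * y * l2
    z2 = z * z * l2
    k = np.sign(rr) * rr * rr * x2
    d_cyl = (np.sqrt(np.maximum(x2 * a2 * il2, 0.0)) + y * rr) * il2 - r1
    d_b = np.sqrt(x2 + z2) * il2 - r2
    d_a = np.sqrt(x2 + y2) * il2 - r1
    out = np.where(np.sign(z) * a2 * z2 > k, d_b, np.where(np.sign(y) * a2 * y2 < k, d_a, d_cyl))
    return out


def _smooth_min(d1, d2, k=_BLEND_K):
    h = np.maximum(k - np.abs(d1 - d2), 0.0) / k
    return np.minimum(d1, d2) - h * h * k * 0.25


def tooth_signed_distance(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Signed level-set (negative inside) of the phantom at ``points``."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    d = _sd_superellipsoid(
        pts, spec.crown_half_axes, _CUSP_PATTERN.get(spec.tooth_kind, ())
    )
    # mesiodistal compression of the root cross-sections
    squeeze = np.array([1.0, 1.0 / _ROOT_Y_SCALE[spec.tooth_kind], 1.0])
    for root in spec.root_specs:
        base, tip = root.base_point, root.tip_point
        dr = _sd_round_cone(
            pts * squeeze, base * squeeze, tip * squeeze,
            root.base_radius, root.tip_radius,
        )
        d = _smooth_min(d, dr)
    return d


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def make_phantom(tooth_kind: str, seed: int, pitch: float = 0.15):
    """Generate the ground-truth mesh of one synthetic tooth.

    Parameters
    ----------
    tooth_kind
        One of ``premolar``, ``canine``, ``molar``.
    seed
        Stored in the spec for downstream stochastic stages; the geometry
        itself is deterministic per kind.
    pitch
        Marching-cubes sampling pitch in mm. The default is finer than the
        0.2 mm CBCT voxel so the ground truth is not the fidelity bottleneck.

    Returns
    -------
    (PhantomSpec, SurfaceMesh)
        The spec and a closed, outward-oriented surface mesh.
    """
    if tooth_kind not in _KIND_PARAMS:
        raise ValueError(
            f"unknown tooth_kind {tooth_kind!r}; expected one of {TOOTH_KINDS}"
        )
    p = _KIND_PARAMS[tooth_kind]
    spec = PhantomSpec(
        tooth_kind=tooth_kind,
        crown_half_axes=p["crown"],
        root_specs=p["roots"],
        canal_radius=p["canal"],
        seed=int(seed),
    )

    pts = [spec.crown_half_axes, tuple(-x for x in spec.crown_half_axes)]
    for r in spec.root_specs:
        for q in (r.base_point, r.tip_point):
            pts.append(tuple(q + r.base_radius))
            pts.append(tuple(q - r.base_radius))
    pts = np.array(pts)
    lo = pts.min(axis=0) - 1.5
    hi = pts.max(axis=0) + 1.5

    nx, ny, nz = (np.ceil((hi - lo) / pitch).astype(int) + 1)
    xs = lo[0] + np.arange(nx) * pitch
    ys = lo[1] + np.arange(ny) * pitch
    zs = lo[2] + np.arange(nz) * pitch
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    f = tooth_signed_distance(spec, grid.reshape(-1, 3)).reshape(nx, ny, nz)

    verts, faces, _, _ = measure.marching_cubes(
        -f, level=0.0, spacing=(pitch, pitch, pitch)
    )
    mesh = SurfaceMesh(verts + lo, faces.astype(np.int64))
    if mesh.volume < 0:
        mesh = mesh.flipped()
    return spec, mesh


def canal_segments(spec: PhantomSpec):
    """Root-canal center lines as (start, end, radius) triples.

    Each canal runs from inside the crown to 1.5 mm short of the root apex,
    so the low-density channel is fully enclosed by hard tissue (the
    apex-open variant is produced by extending ``end`` past the tip).
    """
    out = []
    for root, radius in zip(spec.root_specs, spec.canal_radius):
        start = root.base_point + np.array([0.0, 0.0, 2.0])
        end = root.base_point + root.axis * max(root.length - 1.5, 0.1)
        out.append((start, end, float(radius)))
    return out


def deformity_site(spec: PhantomSpec, mesh: SurfaceMesh, site: str) -> np.ndarray:
    """Surface point of a named deviation region.

    ``root_tip``: apex of the first root; ``furcation``: the saddle between
    roots of a multi-rooted phantom; ``crown``: a buccal crown patch (the
    chipped-filling stand-in).
    """
    a, b, c = spec.crown_half_axes
    if site == "root_tip":
        probe = spec.root_specs[0].tip_point + np.array([0.0, 0.0, -2.0])
    elif site == "furcation":
        if len(spec.root_specs) < 2:
            raise ValueError("furcation requires a multi-rooted phantom")
        bases = np.stack([r.base_point for r in spec.root_specs])
        probe = bases.mean(axis=0)
        probe[2] -= 2.0
    elif site == "crown":
        probe = np.array([0.0, b + 2.0, 0.4 * c])
    else:
        raise ValueError(f"unknown site {site!r}")
    _, cp, _ = mesh.query().closest_point(probe[None])
    return cp[0]


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def voxelize(
    mesh: SurfaceMesh,
    spacing: float = 0.2,
    hu_hard_tissue: float = 2000.0,
    hu_canal: float = 300.0,
    hu_background: float = 0.0,
    blur_sigma: float = 0.0,
    noise_sd: float = 0.0,
    canal_paths=None,
    seed: int = 0,
    pad_voxels: int = 5,
) -> VoxelVolume:
    """Render a closed mesh into a CBCT-like HU volume.

    Voxel centers inside the mesh receive ``hu_hard_tissue`` except along
    canal paths (cylindrical channels) which receive ``hu_canal``; outside
    is ``hu_background``. A Gaussian blur of physical width ``blur_sigma``
    (mm) emulates the scanner point-spread / partial-volume effect and
    seeded Gaussian noise of ``noise_sd`` (HU) emulates detector noise. The
    grid is padded with ``pad_voxels`` background voxels on every side so
    the surface never touches the grid boundary.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if blur_sigma < 0 or noise_sd < 0:
        raise ValueError("blur_sigma and noise_sd must be >= 0")
    if not (hu_hard_tissue > SEGMENTATION_THRESHOLD_HU > hu_background):
        raise ValueError(
            "hu_hard_tissue and hu_background must straddle the "
            f"{SEGMENTATION_THRESHOLD_HU:.0f} HU segmentation threshold"
        )
    if not mesh.is_closed():
        raise GeometryError("mesh must be closed (inside test undefined)")

    sp = np.full(3, float(spacing))
    lo = mesh.vertices.min(axis=0) - pad_voxels * sp
    hi = mesh.vertices.max(axis=0) + pad_voxels * sp
    shape = tuple(np.ceil((hi - lo) / sp).astype(int) + 1)
    inside = voxelize_solid(mesh, sp, lo, shape)

    values = np.full(shape, float(hu_background))
    values[inside] = float(hu_hard_tissue)

    if canal_paths:
        for start, end, radius in canal_paths:
            _carve_cylinder(values, inside, sp, lo, start, end, radius, hu_canal)

    if blur_sigma > 0:
        values = ndimage.gaussian_filter(values, sigma=blur_sigma / sp)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return VoxelVolume(values, sp, lo)


def _carve_cylinder(values, inside, spacing, origin, start, end, radius, hu_canal):
    """Set voxels within ``radius`` of segment start-end (and inside the
    tooth) to the canal HU. Works on the bounding box of the segment."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    lo = np.minimum(start, end) - radius - spacing
    hi = np.maximum(start, end) + radius + spacing
    i0 = np.maximum(np.floor((lo - origin) / spacing), 0).astype(int)
    i1 = np.minimum(
        np.ceil((hi - origin) / spacing), np.array(values.shape) - 1
    ).astype(int)
    idx = np.meshgrid(
        *[np.arange(i0[k], i1[k] + 1) for k in range(3)], indexing="ij"
    )
    centers = origin + np.stack(idx, axis=-1) * spacing
    d = centers - start
    axis = end - start
    l2 = float(axis @ axis)
    t = np.clip((d @ axis) / l2, 0.0, 1.0)
    perp = d - t[..., None] * axis
    in_cyl = (perp ** 2).sum(axis=-1) <= radius * radius
    sl = tuple(slice(i0[k], i1[k] + 1) for k in range(3))
    region = in_cyl & inside[sl]
    values[sl][region] = float(hu_canal)


# ---------------------------------------------------------------------------
# surface deformations
# ---------------------------------------------------------------------------


def deform_bump(
    mesh: SurfaceMesh, center: np.ndarray, radius: float, amplitude: float
) -> SurfaceMesh:
    """Displace vertices near ``center`` along their outward normals.

    The displacement is ``amplitude * w(d)`` with the cosine taper
    ``w(d) = (1 + cos(pi d / radius)) / 2``, so w(0) = 1 and w(radius) = 0.
    Negative amplitude produces a dent. Vertices outside the support are
    returned bit-identical.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=np.float64).reshape(3)
    d = np.linalg.norm(mesh.vertices - center, axis=1)
    mask = d < radius
    if amplitude == 0 or not mask.any():
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    w = 0.5 * (1.0 + np.cos(np.pi * d[mask] / radius))
    verts = mesh.vertices.copy()
    verts[mask] += (amplitude * w)[:, None] * mesh.vertex_normals()[mask]
    return SurfaceMesh(verts, mesh.faces.copy())


def _adjacency(mesh: SurfaceMesh) -> sparse.csr_matrix:
    e = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    n = mesh.n_vertices
    m = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    ).tocsr()
    m = ((m + m.T) > 0).astype(np.float64)
    return m


def laplacian_smooth(
    mesh: SurfaceMesh, iterations: int = 1, lam: float = 0.5
) -> SurfaceMesh:
    """Uniform-weight Laplacian smoothing (kept mild: it shrinks slightly)."""
    if iterations <= 0:
        return mesh
    adj = _adjacency(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = v + lam * (adj @ v / deg[:, None] - v)
    return SurfaceMesh(v, mesh.faces.copy())


def simulate_replica(
    mesh: SurfaceMesh,
    milling_noise_sd: float,
    seed: int,
    smooth_iterations: int = 1,
    smooth_lambda: float = 0.5,
) -> SurfaceMesh:
    """Stochastic stand-in for subtractive fabrication of the replica.

    Each vertex is displaced along its normal by i.i.d. zero-mean Gaussian
    noise of sd ``milling_noise_sd`` (mm), followed by a mild Laplacian
    smoothing pass that keeps the perturbed surface manifold-looking (a
    milling tool cannot produce per-vertex jitter). With sd = 0 the mesh is
    returned unchanged.
    """
    if milling_noise_sd < 0:
        raise ValueError("milling_noise_sd must be >= 0")
    if milling_noise_sd == 0:
        return SurfaceMesh(mesh.vertices.copy(), mesh.faces.copy())
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, milling_noise_sd, size=mesh.n_vertices)
    verts = mesh.vertices + disp[:, None] * mesh.vertex_normals()
    noisy = SurfaceMesh(verts, mesh.faces.copy())
    return laplacian_smooth(noisy, smooth_iterations, smooth_lambda)
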