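"""Surface-based rigid registration.

Point-to-point ICP with exact closest-point-on-surface correspondences
(point to triangle, not nearest vertex). The inner least-squares step is
the weighted Kabsch solution via SVD of the cross-covariance with the
determinant correction, so the result is always a proper rotation.

The RMS history recorded by :func:`icp_register` is evaluated on a fixed
(optionally seeded-subsampled) set of source vertices; with untrimmed exact
correspondences it is monotonically non-increasing — each least-squares
update cannot raise the RMS against the previous correspondences, and
switching to the new closest points can only lower it further.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .geometry import SurfaceMesh

__all__ = [
    "RegistrationError",
    "RigidTransform",
    "ICPConfig",
    "ICPResult",
    "best_rigid",
    "initial_align",
    "initial_align_candidates",
    "icp_register",
    "merge_half_scans",
]

logger = logging.getLogger("replica_accuracy")


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (mm)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        )
        object.__setattr__(
            self,
            "translation",
            np.asarray(self.translation, dtype=np.float64).reshape(3),
        )
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (tol 1e-9)")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg, translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        th = np.deg2rad(angle_deg)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        r = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
        return cls(_orthonormalize(r), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: SurfaceMesh) -> SurfaceMesh:
        return mesh.with_vertices(self.apply(mesh.vertices))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            _orthonormalize(self.rotation @ other.rotation),
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _orthonormalize(r: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (keeps invariants exact under
    repeated composition)."""
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt




def _referenced(mesh: SurfaceMesh) -> np.ndarray:
    """Vertices actually used by faces. Partial meshes may carry a larger
    shared vertex array; registration must only ever see the surface's own
    points."""
    return mesh.vertices[np.unique(mesh.faces)]


@dataclass(frozen=True)
class ICPConfig:
    """ICP controls. ``subsample_count`` of None uses every source vertex;
    ``trim_fraction`` discards that fraction of the worst correspondences
    each iteration (robustness for partially overlapping surfaces, at the
    cost of the monotone-RMS guarantee). Convergence is an absolute change
    of the correspondence RMS below ``rms_change_tolerance`` (mm)."""

    max_iterations: int = 100
    rms_change_tolerance: float = 1e-6
    correspondence_cutoff: float = np.inf
    trim_fraction: float = 0.0
    subsample_count: int | None = None
    seed: int = 0
    use_initial_align: bool = True

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rms_change_tolerance <= 0:
            raise ValueError("rms_change_tolerance must be > 0")
        if not 0 <= self.trim_fraction < 1:
            raise ValueError("trim_fraction must be in [0, 1)")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_history: list
    final_rms: float
    n_iterations: int


# ---------------------------------------------------------------------------
# closed-form rigid fit
# ---------------------------------------------------------------------------


def best_rigid(
    source_points: np.ndarray,
    target_points: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Least-squares proper rigid transform mapping paired sources onto
    targets: minimizes sum w_i ||R s_i + t - t_i||^2 (Kabsch, SVD with
    determinant correction, no scaling)."""
    s = np.asarray(source_points, dtype=np.float64)
    t = np.asarray(target_points, dtype=np.float64)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("paired (n, 3) point sets required")
    n = len(s)
    if n < 3:
        raise RegistrationError("need at least 3 point pairs")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    sc = s - (w @ s)
    tc = t - (w @ t)
    h = (sc * w[:, None]).T @ tc
    u, sv, vt = np.linalg.svd(h)
    # rank-deficiency: collinear/coincident configurations leave the
    # rotation about the degenerate axis unconstrained
    if sv[1] < 1e-12 * max(sv[0], 1e-30):
        raise RegistrationError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    r = _orthonormalize(r)
    trans = (w @ t) - r @ (w @ s)
    return RigidTransform(r, trans)


# ---------------------------------------------------------------------------
# coarse initialization
# ---------------------------------------------------------------------------


def _principal_axes(points: np.ndarray):
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return c, evals[order], evecs[:, order]


def _sampled_rms(source_pts, target: SurfaceMesh, transform, n=500, seed=0):
    rng = np.random.default_rng(seed)
    idx = (
        rng.choice(len(source_pts), n, replace=False)
        if len(source_pts) > n
        else np.arange(len(source_pts))
    )
    d = target.query().distances(transform.apply(source_pts[idx]))
    return float(np.sqrt(np.mean(d * d)))


def initial_align_candidates(source: SurfaceMesh, target: SurfaceMesh):
    """Ranked coarse-alignment candidates by centroids and principal axes.

    The four proper sign assignments of the principal frame, the identity
    and a pure centroid shift are scored by sampled closest-point RMS and
    returned best-first. Nearly isotropic shapes (principal moments within
    5%) keep only the centroid candidates, since their axes carry no
    information. A near-symmetric shape can make a wrong sign assignment
    score *better* than a merely misaligned true pose, so callers that must
    be robust refine several candidates (see :func:`icp_register`).
    """
    cs, es, vs = _principal_axes(_referenced(source))
    ct, et, vt = _principal_axes(_referenced(target))

    candidates = [RigidTransform.identity(), RigidTransform(np.eye(3), ct - cs)]
    isotropic = es[0] - es[2] < 0.05 * max(es[0], 1e-30)
    if isotropic:
        logger.info("initial_align: near-isotropic source, centroid-only")
    else:
        for sx in (1.0, -1.0):
            for sy in (1.0, -1.0):
                flip = np.diag([sx, sy, sx * sy])  # proper by construction
                r = vt @ flip @ vs.T
                r = _orthonormalize(r)
                candidates.append(RigidTransform(r, ct - r @ cs))
    scores = [_sampled_rms(_referenced(source), target, c) for c in candidates]
    order = np.argsort(scores)
    return [candidates[i] for i in order]


def initial_align(source: SurfaceMesh, target: SurfaceMesh) -> RigidTransform:
    """Best coarse alignment candidate (see initial_align_candidates)."""
    return initial_align_candidates(source, target)[0]


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------


def _params(t: RigidTransform) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return np.concatenate(
        [Rotation.from_matrix(t.rotation).as_rotvec(), t.translation]
    )


def _from_params(p: np.ndarray) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    return RigidTransform(Rotation.from_rotvec(p[:3]).as_matrix(), p[3:])


def _icp_loop(pts, tq, transform, cfg: ICPConfig, max_iterations: int):
    """Core ICP iteration from a given start; returns (transform,
    rms_history, n_iterations).

    The recorded history is the untrimmed RMS of the point set; with
    trimming active the stopping rule instead watches the
    kept-correspondence RMS, which settles even when non-overlap vertices
    dominate the full-set value.

    ICP converges only linearly when the residual motion slides along a
    low-curvature direction of the RMS landscape (e.g. rotation about a
    shape's long axis); when the recent transform updates form a decaying
    geometric sequence, the sequence is extrapolated to its limit and the
    jump accepted only if it does not raise the RMS, so the monotonicity
    guarantee is untouched.
    """
    trimming = cfg.trim_fraction > 0 or np.isfinite(cfg.correspondence_cutoff)
    rms_history: list[float] = []
    stop_rms_prev = np.inf
    n_iter = 0
    param_trail: list[np.ndarray] = [_params(transform)]
    for n_iter in range(1, max(max_iterations, 1) + 1):
        moved = transform.apply(pts)
        d, cp, _ = tq.closest_point(moved)
        rms = float(np.sqrt(np.mean(d * d)))
        rms_history.append(rms)
        keep = np.ones(len(pts), dtype=bool)
        if trimming:
            keep &= d <= cfg.correspondence_cutoff
            if cfg.trim_fraction > 0 and keep.sum() > 3:
                cut = np.quantile(d[keep], 1.0 - cfg.trim_fraction)
                keep &= d <= cut
            if keep.sum() < 3:
                raise RegistrationError("no correspondences survive trimming")
        transform = best_rigid(pts[keep], cp[keep])
        param_trail.append(_params(transform))

        if not trimming and len(param_trail) >= 3 and n_iter % 4 == 0:
            d1 = param_trail[-1] - param_trail[-2]
            d2 = param_trail[-2] - param_trail[-3]
            n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
            if n2 > 0 and n1 > 0:
                ratio = n1 / n2
                aligned = float(d1 @ d2) / (n1 * n2)
                if 0.2 < ratio < 0.995 and aligned > 0.95:
                    jump = min(ratio / (1.0 - ratio), 50.0)
                    candidate = _from_params(param_trail[-1] + d1 * jump)
                    d_c = tq.closest_point(candidate.apply(pts))[0]
                    if float(np.sqrt(np.mean(d_c * d_c))) <= rms:
                        transform = candidate
                        param_trail.append(_params(transform))

        stop_rms = float(np.sqrt(np.mean(d[keep] ** 2))) if trimming else rms
        if abs(stop_rms_prev - stop_rms) < cfg.rms_change_tolerance:
            break
        stop_rms_prev = stop_rms
    return transform, rms_history, n_iter


def icp_register(
    source: SurfaceMesh,
    target: SurfaceMesh,
    cfg: ICPConfig | None = None,
) -> ICPResult:
    """Register ``source`` onto ``target``.

    Iterates exact closest-point-on-surface correspondence, optional
    cutoff/trimming, and the closed-form rigid fit, solving each iteration
    for the absolute transform from the original source positions (numerically
    stabler than incremental composition). Returns the transform, the
    per-iteration correspondence RMS history, the final RMS over all source
    vertices, and the iteration count.
    """
    cfg = cfg or ICPConfig()
    tq = target.query()
    pts = _referenced(source)
    if cfg.subsample_count is not None and cfg.subsample_count < len(pts):
        rng = np.random.default_rng(cfg.seed)
        idx = rng.choice(len(pts), cfg.subsample_count, replace=False)
        pts = pts[idx]

    if cfg.use_initial_align:
        # multi-start: a near-symmetric shape can make a flipped principal
        # frame score better than the true-but-misaligned pose, and plain
        # ICP cannot escape that local minimum; briefly refining the top
        # candidates and keeping the best resolves the ambiguity
        starts = initial_align_candidates(source, target)[:3]
        warmups = [
            _icp_loop(pts, tq, t0, cfg, max_iterations=min(8, cfg.max_iterations))
            for t0 in starts
        ]
        best = int(np.argmin([w[1][-1] for w in warmups]))
        transform, rms_history, n_warm = warmups[best]
    else:
        transform, rms_history, n_warm = RigidTransform.identity(), [], 0

    transform, tail, n_iter = _icp_loop(
        pts, tq, transform, cfg, cfg.max_iterations - n_warm
    )
    rms_history = rms_history + tail
    n_iter += n_warm

    # converged transform's own RMS closes the history
    d_final = tq.closest_point(transform.apply(pts))[0]
    rms_history.append(float(np.sqrt(np.mean(d_final * d_final))))

    all_pts = _referenced(source)
    trimming = cfg.trim_fraction > 0 or np.isfinite(cfg.correspondence_cutoff)
    if len(pts) < len(all_pts) and not trimming:
        # one full-vertex polish after subsampled convergence
        d_all, cp_all, _ = tq.closest_point(transform.apply(all_pts))
        transform = best_rigid(all_pts, cp_all)

    d_all = tq.closest_point(transform.apply(all_pts))[0]
    return ICPResult(
        transform=transform,
        rms_history=rms_history,
        final_rms=float(np.sqrt(np.mean(d_all * d_all))),
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# partial-scan merging
# ---------------------------------------------------------------------------


def merge_half_scans(
    half_a: SurfaceMesh,
    half_b: SurfaceMesh,
    cfg: ICPConfig | None = None,
    weld_tol: float = 1e-6,
    overlap_margin: float = 1.0,
    min_overlap_fraction: float = 0.1,
) -> SurfaceMesh:
    """Register ``half_b`` onto ``half_a`` and combine into one mesh.

    The halves are assumed to arrive roughly pre-aligned in a common
    scanner frame (within ``overlap_margin`` mm) and to agree only over an
    overlap band. Plain trimmed ICP fails here: vertices beyond the band
    find their closest points near the cut rim of the other half and drag
    the fit along the surface ("swallowing"). Two rejection rules fix
    this: a correspondence is used only if its closest point lies farther
    than ``overlap_margin`` from the rim of the fixed half (the classic
    zippering rule, widened to a physical margin) and no farther than
    ``overlap_margin`` from its source point. A narrow overlap ring on a
    smooth surface still converges only linearly along its
    weakly-constrained directions, so the same geometric-sequence
    extrapolation used by the main ICP accelerates the tail.

    After registration the triangle sets are concatenated and duplicate
    vertices welded within ``weld_tol`` mm. A result whose overlap
    (vertices of b within 0.1 mm of a) stays below
    ``min_overlap_fraction`` is rejected: a true overlap band is an area
    covering a sizable vertex fraction, whereas disjoint cuts snapped
    together only touch along a curve.
    """
    from scipy.spatial import cKDTree

    cfg = cfg or ICPConfig()
    tq = half_a.query()
    # distance from each face of the fixed half to its open rim
    boundary_faces = half_a.boundary_faces()
    if boundary_faces.any():
        edges = np.sort(
            half_a.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        rim_mid = half_a.vertices[uniq[counts == 1]].mean(axis=1)
        centroids = half_a.triangles.mean(axis=1)
        face_rim_d = cKDTree(rim_mid).query(centroids)[0]
    else:
        face_rim_d = np.full(half_a.n_faces, np.inf)

    pts = _referenced(half_b)
    if cfg.subsample_count is not None and cfg.subsample_count < len(pts):
        rng = np.random.default_rng(cfg.seed)
        pts = pts[rng.choice(len(pts), cfg.subsample_count, replace=False)]

    def kept(d, fidx):
        return (d <= overlap_margin) & (face_rim_d[fidx] > overlap_margin)

    transform = RigidTransform.identity()
    trail = [_params(transform)]
    prev_rms = np.inf
    for n_iter in range(3 * cfg.max_iterations):
        moved = transform.apply(pts)
        d, cp, fidx = tq.closest_point(moved)
        keep = kept(d, fidx)
        if keep.sum() < 3:
            raise RegistrationError(
                "no interior overlap correspondences; halves do not overlap"
            )
        transform = best_rigid(pts[keep], cp[keep])
        trail.append(_params(transform))
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        if len(trail) >= 3 and n_iter % 4 == 0:
            d1 = trail[-1] - trail[-2]
            d2 = trail[-2] - trail[-3]
            n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
            if n1 > 0 and n2 > 0:
                ratio = n1 / n2
                aligned = float(d1 @ d2) / (n1 * n2)
                if 0.2 < ratio < 0.999 and aligned > 0.95:
                    cand = _from_params(
                        trail[-1] + d1 * min(ratio / (1.0 - ratio), 200.0)
                    )
                    dc, _, fc = tq.closest_point(cand.apply(pts))
                    kc = kept(dc, fc)
                    if (
                        kc.sum() >= 3
                        and float(np.sqrt(np.mean(dc[kc] ** 2))) <= rms
                    ):
                        transform = cand
                        trail.append(_params(transform))
        if abs(prev_rms - rms) < cfg.rms_change_tolerance:
            break
        prev_rms = rms

    moved = transform.apply_mesh(half_b)
    d = half_a.query().distances(_referenced(moved))
    overlap = float(np.mean(d < 0.1))
    if overlap < min_overlap_fraction:
        raise RegistrationError(
            f"halves barely overlap after registration ({overlap:.1%} of "
            "vertices within 0.1 mm); refusing to merge"
        )
    verts = np.vstack([half_a.vertices, moved.vertices])
    faces = np.vstack([half_a.faces, moved.faces + half_a.n_vertices])
    return SurfaceMesh(verts, faces).welded(weld_tol)
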