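"""Independent brute-force oracles used by the tests.

These deliberately use different algorithms from the package kernel:
point-to-triangle distance via plane projection plus edge-segment
distances, containment via direct crossing counts against every face, and
plane-slice loop counting via union-find over intersection segments.
"""

import numpy as np


def point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0.0, 1.0)
    return np.linalg.norm(p - (a + t * ab))


def point_triangle_distance(p, a, b, c):
    """Plane-projection formulation: if the orthogonal projection falls
    inside the triangle the plane distance is the answer, otherwise the
    minimum distance to the three edge segments."""
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    edge_d = min(
        point_segment_distance(p, a, b),
        point_segment_distance(p, b, c),
        point_segment_distance(p, c, a),
    )
    if nn < 1e-300:
        return edge_d
    n = n / np.sqrt(nn)
    proj = p - np.dot(p - a, n) * n
    # barycentric test of the projection
    v0, v1, v2 = b - a, c - a, proj - a
    d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
    d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
    denom = d00 * d11 - d01 * d01
    if abs(denom) < 1e-300:
        return edge_d
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    if v >= 0 and w >= 0 and v + w <= 1:
        return abs(np.dot(p - a, n))
    return edge_d


def brute_closest_distance(p, mesh):
    tri = mesh.triangles
    return min(point_triangle_distance(p, t[0], t[1], t[2]) for t in tri)


def brute_line_hits(origin, direction, mesh):
    """All signed line parameters t where origin + t*direction crosses a
    face, via per-face solving in a 2D frame orthogonal to the direction."""
    d = direction / np.linalg.norm(direction)
    ts = []
    for t in mesh.triangles:
        a, b, c = t
        m = np.column_stack([b - a, c - a, -d])
        rhs = origin - a
        try:
            u, v, tt = np.linalg.solve(m, rhs)
        except np.linalg.LinAlgError:
            continue
        if u >= -1e-12 and v >= -1e-12 and u + v <= 1 + 1e-12:
            ts.append(float(tt))
    return sorted(ts)


def brute_contains(points, mesh):
    """Parity of +z crossings counted per face, with a generic-position
    nudge of the query points."""
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        q = p + np.array([3.1e-7, 1.7e-7, 0.0])
        hits = brute_line_hits(q, np.array([0.0, 0.0, 1.0]), mesh)
        out[i] = sum(1 for t in hits if t > 0) % 2 == 1
    return out


def slice_loop_count(mesh, z):
    """Number of closed loops in the cross-section of the mesh at height z,
    via union-find over the face/plane intersection segments."""
    segments = []
    for t in mesh.triangles:
        zs = t[:, 2] - z
        pts = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            zi, zj = zs[i], zs[j]
            if (zi > 0) != (zj > 0):
                w = zi / (zi - zj)
                pts.append(t[i] + w * (t[j] - t[i]))
        if len(pts) == 2:
            segments.append((pts[0][:2], pts[1][:2]))
    if not segments:
        return 0
    # union-find on endpoint keys
    keys = {}

    def key(p):
        return (round(p[0], 6), round(p[1], 6))

    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for a, b in segments:
        union(key(a), key(b))
    roots = {find(k) for k in parent}
    return len(roots)


def best_proper_rotation_residual(source, target, n_grid=24, refine=True):
    """Brute-force minimum RMS over proper rotations (+ optimal translation)
    for paired point sets: coarse search over an Euler-angle grid followed
    by local polishing."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    s = source - source.mean(axis=0)
    t = target - target.mean(axis=0)

    def rms(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        d = s @ r.T - t
        return np.sqrt((d**2).sum(axis=1).mean())

    angles = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    best = (np.inf, None)
    for a in angles:
        for b in np.linspace(0, np.pi, n_grid // 2):
            for c in angles:
                rv = Rotation.from_euler("zyz", [a, b, c]).as_rotvec()
                v = rms(rv)
                if v < best[0]:
                    best = (v, rv)
    if refine:
        res = minimize(rms, best[1], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if res.fun < best[0]:
            best = (res.fun, res.x)
    return best[0]
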