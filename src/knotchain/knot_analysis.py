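"""Open-chain knot localization.

The pipeline is: close an open arc into a ring with a minimally
interfering closure, classify the ring through the Alexander
determinants |Delta(-1)| and |Delta(-2)|, search for the shortest arc
carrying a target topology, split a composite two-trefoil chain into
its prime components via excision tests, and assign a handedness to
each trefoil from the sign of its space writhe.

Everything here is deterministic: random projection retries draw from a
generator seeded per call.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ProjectionError, WrongTopologyError
from .model_core import Conformation

__all__ = [
    "ClosedPolygon",
    "TopologyLabel",
    "KnotRecord",
    "close_arc_mic",
    "alexander_determinants",
    "classify_topology",
    "shortest_knotted_arc",
    "find_prime_components",
    "handedness",
    "writhe",
]

#: (det at -1, odd part of det at -2) -> label
_CLASS_TABLE = {
    (1, 1): "unknot",
    (3, 7): "trefoil",
    (9, 49): "composite_3131",
}

#: Minimum bead count of an arc that can possibly close into a trefoil.
MIN_TREFOIL_ARC = 6


@dataclass
class ClosedPolygon:
    """Closed polygonal curve; vertices are cyclic (no repeated first
    vertex at the end)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (M, 3) array")
        if len(self.vertices) < 3:
            raise ValueError("a closed polygon needs at least 3 vertices")
        closed_diff = np.roll(self.vertices, -1, axis=0) - self.vertices
        if np.any(np.linalg.norm(closed_diff, axis=1) == 0):
            raise ValueError("consecutive vertices coincide")


@dataclass
class TopologyLabel:
    det_m1: int
    det_m2: int
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = _CLASS_TABLE.get((self.det_m1, self.det_m2), "other")


@dataclass
class KnotRecord:
    """Per-frame localization result for a two-trefoil chain.

    ``isolated_arcs`` holds 0-based inclusive (start, end) bead indices
    with a handedness of +1, -1, or 0 for unknown. ``boundary_contact``
    flags frames where any reported arc includes a tethered terminus.
    """

    frame_index: int
    isolated_arcs: List[Tuple[int, int, int]]
    composite_arc: Optional[Tuple[int, int]] = None
    boundary_contact: bool = False

    @property
    def n_isolated(self) -> int:
        return len(self.isolated_arcs)


# ---------------------------------------------------------------------------
# projection and crossing diagram


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _find_crossings(pts: np.ndarray, rot: np.ndarray):
    """Crossings of the closed polygon *pts* projected along z after
    rotation *rot*.

    Returns a list of (i, j, s, t, over_is_i, sign) or None when the
    projection is degenerate (a crossing too close to a vertex, or an
    ambiguous over/under assignment).
    """
    p = pts @ rot.T
    m = len(p)
    a = p
    d = np.roll(p, -1, axis=0) - p
    scale = float(np.max(np.abs(p))) + 1.0

    ii, jj = np.triu_indices(m, k=1)
    adjacent = (jj == ii + 1) | ((ii == 0) & (jj == m - 1))
    ii, jj = ii[~adjacent], jj[~adjacent]

    det = d[ii, 0] * d[jj, 1] - d[ii, 1] * d[jj, 0]
    nonpar = np.abs(det) > 1e-12 * scale * scale
    ii, jj, det = ii[nonpar], jj[nonpar], det[nonpar]

    rx = a[jj, 0] - a[ii, 0]
    ry = a[jj, 1] - a[ii, 1]
    s = (rx * d[jj, 1] - ry * d[jj, 0]) / det
    t = (rx * d[ii, 1] - ry * d[ii, 0]) / det

    inside = (s > -1e-9) & (s < 1 + 1e-9) & (t > -1e-9) & (t < 1 + 1e-9)
    ii, jj, s, t = ii[inside], jj[inside], s[inside], t[inside]
    if len(ii) == 0:
        return []

    margin = 1e-7
    if np.any((s < margin) | (s > 1 - margin) | (t < margin) | (t > 1 - margin)):
        return None
    zi = a[ii, 2] + s * d[ii, 2]
    zj = a[jj, 2] + t * d[jj, 2]
    if np.any(np.abs(zi - zj) < 1e-9 * scale):
        return None

    over_is_i = zi > zj
    # crossing sign: with over-strand direction o and under-strand
    # direction u, positive when (o x u)_z > 0
    oi = np.where(over_is_i[:, None], d[ii], d[jj])
    ui = np.where(over_is_i[:, None], d[jj], d[ii])
    cz = oi[:, 0] * ui[:, 1] - oi[:, 1] * ui[:, 0]
    if np.any(cz == 0):
        return None
    sgn = np.where(cz > 0, 1, -1)
    return list(zip(ii.tolist(), jj.tolist(), s.tolist(), t.tolist(),
                    over_is_i.tolist(), sgn.tolist()))


def _generic_crossings(pts: np.ndarray, seed: int = 0, max_tries: int = 50):
    """Find crossings under a generic projection, retrying with random
    rotations (deterministic in *seed*)."""
    rng = np.random.default_rng(seed)
    cr = _find_crossings(pts, np.eye(3))
    if cr is not None:
        return cr
    for _ in range(max_tries):
        cr = _find_crossings(pts, _random_rotation(rng))
        if cr is not None:
            return cr
    raise ProjectionError(
        f"no generic projection in {max_tries} tries for a "
        f"{len(pts)}-vertex polygon"
    )


def _bareiss_det(mat: List[List[int]]) -> int:
    """Exact determinant of an integer matrix (fraction-free Gaussian
    elimination); avoids float overflow for large Alexander matrices."""
    n = len(mat)
    if n == 0:
        return 1
    m = [row[:] for row in mat]
    sign = 1
    prev = 1
    for k in range(n - 1):
        if m[k][k] == 0:
            for r in range(k + 1, n):
                if m[r][k] != 0:
                    m[k], m[r] = m[r], m[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                m[i][j] = (m[i][j] * m[k][k] - m[i][k] * m[k][j]) // prev
        prev = m[k][k]
    return sign * m[n - 1][n - 1]


def alexander_determinants(poly: ClosedPolygon, seed: int = 0) -> Tuple[int, int]:
    """Alexander determinants (|Delta(-1)|, |Delta(-2)|) of a closed
    polygon.

    The diagram is built from a generic planar projection (random
    rotations are retried until no crossing is degenerate). Because the
    matrix determinant carries a +-t^k ambiguity, the value at t = -2 is
    reduced to its odd part; at t = -1 the ambiguity is a sign only.
    """
    crossings = _generic_crossings(poly.vertices, seed=seed)
    if not crossings:
        return (1, 1)

    # underpass events ordered along the curve
    events = []  # (segment, parameter, crossing id)
    for cid, (i, j, s, t, over_is_i, sgn) in enumerate(crossings):
        if over_is_i:
            events.append((j, t, cid))
        else:
            events.append((i, s, cid))
    events.sort()
    k_cross = len(events)
    upos = [(seg, par) for seg, par, _ in events]

    def arc_of(seg: int, par: float) -> int:
        # generator arc k runs from underpass k to underpass k+1
        return (bisect.bisect_right(upos, (seg, par)) - 1) % k_cross

    rows = []
    for k, (seg, par, cid) in enumerate(events):
        i, j, s, t, over_is_i, sgn = crossings[cid]
        oseg, opar = (i, s) if over_is_i else (j, t)
        rows.append((k, (k - 1) % k_cross, k, arc_of(oseg, opar), sgn))

    def _det_at(tval: int) -> int:
        mat = [[0] * k_cross for _ in range(k_cross)]
        for k, gin, gout, gover, sgn in rows:
            if gover == gin or gover == gout:
                mat[k][gin] += -1
                mat[k][gout] += 1
            elif sgn > 0:
                mat[k][gin] += 1
                mat[k][gout] += -tval
                mat[k][gover] += tval - 1
            else:
                mat[k][gin] += -tval
                mat[k][gout] += 1
                mat[k][gover] += tval - 1
        minor = [row[: k_cross - 1] for row in mat[: k_cross - 1]]
        return abs(_bareiss_det(minor))

    d1 = _det_at(-1)
    d2 = _det_at(-2)
    while d2 > 0 and d2 % 2 == 0:
        d2 //= 2
    return (d1, d2)


def classify_topology(det_m1: int, det_m2: int) -> TopologyLabel:
    """Map a determinant pair to one of unknot / trefoil /
    composite_3131 / other. Chirality is deliberately not inferred here;
    the Alexander determinants are blind to it."""
    if det_m1 < 0 or det_m2 < 0:
        raise ValueError("determinants must be nonnegative")
    return TopologyLabel(det_m1=int(det_m1), det_m2=int(det_m2))


# ---------------------------------------------------------------------------
# minimally interfering closure


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    d = pts - pts[0]
    return np.linalg.matrix_rank(d, tol=tol * (np.max(np.abs(d)) + 1.0)) < 2


def _planar_normal(pts: np.ndarray, tol: float = 1e-9):
    """Unit normal if the points are coplanar, else None."""
    d = pts - pts.mean(axis=0)
    scale = np.max(np.abs(d)) + 1.0
    _, sv, vt = np.linalg.svd(d, full_matrices=False)
    if sv[-1] < tol * scale:
        return vt[-1]
    return None


def _hull_distance_and_normal(point: np.ndarray, hull: ConvexHull):
    """Distance from an interior/boundary point to the hull surface and
    the outward normal of the nearest facet."""
    eq = hull.equations  # (n_facets, 4): n.x + b <= 0 inside
    vals = eq[:, :3] @ point + eq[:, 3]
    k = int(np.argmax(vals))  # least negative = nearest facet
    return float(-vals[k]), eq[k, :3]


def close_arc_mic(
    arc: np.ndarray,
    whole_chain_context: Optional[np.ndarray] = None,
    n_sphere_points: int = 12,
) -> ClosedPolygon:
    """Close an open arc into a ring with minimal added entanglement.

    Two closure branches are compared: (a) a direct terminus-to-terminus
    segment, chosen when the terminus separation is smaller than the sum
    of the terminus-to-convex-hull distances; (b) otherwise an outward
    closure that pushes each terminus radially out of the arc's convex
    hull (along the nearest facet's outward normal) to a sphere of twice
    the arc's bounding radius and joins the two exit points with a
    great-circle arc on that sphere.

    ``whole_chain_context`` is accepted for interface compatibility; the
    interference rule is evaluated on the arc's own hull.
    """
    arc = np.asarray(arc, dtype=float)
    if arc.ndim != 2 or arc.shape[1] != 3 or len(arc) < 3:
        raise ValueError("arc must be an (n >= 3, 3) array")

    t1, t2 = arc[0], arc[-1]
    if np.linalg.norm(t1 - t2) == 0:
        # already a ring; drop the duplicate terminus
        return ClosedPolygon(arc[:-1])

    normal = _planar_normal(arc)
    if normal is not None:
        # a planar open arc is always unknotted; close it through an
        # out-of-plane apex so the ring has a resolvable diagram
        centroid = arc.mean(axis=0)
        r = float(np.max(np.linalg.norm(arc - centroid, axis=1))) + 1.0
        apex = centroid + r * normal
        return ClosedPolygon(_dedup(np.vstack([arc, [apex]])))

    try:
        hull = ConvexHull(arc)
    except QhullError:
        raise ValueError("degenerate arc geometry for convex hull")

    q1, n1 = _hull_distance_and_normal(t1, hull)
    q2, n2 = _hull_distance_and_normal(t2, hull)
    if np.linalg.norm(t1 - t2) < q1 + q2:
        return ClosedPolygon(_dedup(arc))

    centroid = arc.mean(axis=0)
    r_bound = float(np.max(np.linalg.norm(arc - centroid, axis=1)))
    r_close = 2.0 * r_bound

    def _to_sphere(p: np.ndarray, normal: np.ndarray) -> np.ndarray:
        nrm = normal / np.linalg.norm(normal)
        # ray p + s*nrm, find s with |p + s*nrm - centroid| = r_close
        w = p - centroid
        b = w @ nrm
        c = w @ w - r_close**2
        s = -b + np.sqrt(b * b - c)
        return p + s * nrm

    e1 = _to_sphere(t1, n1)
    e2 = _to_sphere(t2, n2)

    # great-circle arc from e2 to e1 around the centroid
    v1 = (e2 - centroid) / np.linalg.norm(e2 - centroid)
    v2 = (e1 - centroid) / np.linalg.norm(e1 - centroid)
    cosang = float(np.clip(v1 @ v2, -1.0, 1.0))
    ang = np.arccos(cosang)
    if ang < 1e-12:
        path = []
    else:
        axis = np.cross(v1, v2)
        if np.linalg.norm(axis) < 1e-12:
            # antipodal exits: pick any perpendicular to define the plane
            probe = np.array([1.0, 0.0, 0.0])
            if abs(v1 @ probe) > 0.9:
                probe = np.array([0.0, 1.0, 0.0])
            axis = np.cross(v1, probe)
        axis = axis / np.linalg.norm(axis)
        perp = np.cross(axis, v1)
        angles = np.linspace(0.0, ang, n_sphere_points + 2)[1:-1]
        path = [
            centroid + r_close * (np.cos(a) * v1 + np.sin(a) * perp)
            for a in angles
        ]

    verts = np.vstack([arc, [e2], path, [e1]])
    return ClosedPolygon(_dedup(verts))


def _dedup(pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Drop consecutive (cyclically) duplicated vertices."""
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > tol:
            keep.append(i)
    while len(keep) > 1 and np.linalg.norm(pts[keep[-1]] - pts[keep[0]]) <= tol:
        keep.pop()
    return pts[keep]


def arc_topology(arc: np.ndarray, seed: int = 0) -> TopologyLabel:
    """Convenience: MIC-close an arc and classify it."""
    if len(arc) < 3 or _planar_normal(np.asarray(arc, float)) is not None:
        return classify_topology(1, 1)  # planar arcs cannot be knotted
    poly = close_arc_mic(arc)
    return classify_topology(*alexander_determinants(poly, seed=seed))


# ---------------------------------------------------------------------------
# arc search and prime decomposition


def _positions(chain) -> np.ndarray:
    if isinstance(chain, Conformation):
        return chain.positions
    return np.asarray(chain, dtype=float)


def shortest_knotted_arc(
    chain,
    target: TopologyLabel | str,
    min_len: int = MIN_TREFOIL_ARC,
    seed: int = 0,
) -> Optional[Tuple[int, int]]:
    """Shortest contiguous arc whose MIC closure has the target
    topology; ties broken by the smaller start index.

    Bottom-up scan over arc lengths with early termination: the first
    hit at the shortest length is, by scan order, the answer.
    """
    pos = _positions(chain)
    want = target.label if isinstance(target, TopologyLabel) else str(target)
    n = len(pos)
    for length in range(max(3, min_len), n + 1):
        for s in range(0, n - length + 1):
            lab = arc_topology(pos[s : s + length], seed=seed)
            if lab.label == want:
                return (s, s + length - 1)
    return None


def _excision_is_trefoil(pos: np.ndarray, s: int, e: int, seed: int = 0) -> bool:
    """Excise beads [s, e], rejoin the flanks, and test whether the
    remaining chain still closes into a trefoil."""
    remainder = np.vstack([pos[:s], pos[e + 1 :]])
    if len(remainder) < MIN_TREFOIL_ARC:
        return False
    return arc_topology(remainder, seed=seed).label == "trefoil"


def find_prime_components(
    chain,
    frame_index: int = 0,
    seed: int = 0,
) -> KnotRecord:
    """Locate the prime trefoil components of a two-trefoil chain.

    A candidate arc is *isolated* when excising it and joining its
    flanks leaves a chain whose closure is still a trefoil. Two isolated
    components means the knots are separated; one means they are
    intertwined and the isolated component is the nested knot.
    """
    pos = _positions(chain)
    n = len(pos)
    full = arc_topology(pos, seed=seed)
    if full.label != "composite_3131":
        raise WrongTopologyError(
            f"full-chain closure is {full.label} "
            f"(dets {full.det_m1}, {full.det_m2}), expected composite_3131"
        )

    first = shortest_knotted_arc(pos, "trefoil", seed=seed)
    if first is None:
        raise WrongTopologyError("composite chain without a locatable trefoil arc")
    s1, e1 = first

    # search for a second trefoil arc disjoint from the first
    second = None
    candidates = []
    left = shortest_knotted_arc(pos[: s1], "trefoil", seed=seed) if s1 >= MIN_TREFOIL_ARC else None
    if left is not None:
        candidates.append(left)
    if n - e1 - 1 >= MIN_TREFOIL_ARC:
        right = shortest_knotted_arc(pos[e1 + 1 :], "trefoil", seed=seed)
        if right is not None:
            candidates.append((right[0] + e1 + 1, right[1] + e1 + 1))
    if candidates:
        second = min(candidates, key=lambda a: (a[1] - a[0], a[0]))

    # the composite arc must host two trefoils; starting the length scan
    # above the first trefoil's length skips provably fruitless arcs
    composite = shortest_knotted_arc(
        pos,
        "composite_3131",
        min_len=(e1 - s1 + 1) + MIN_TREFOIL_ARC,
        seed=seed,
    )

    arcs = []
    for (s, e) in filter(None, [first, second]):
        if _excision_is_trefoil(pos, s, e, seed=seed):
            h = handedness(pos, (s, e), seed=seed)
            arcs.append((s, e, h))
    arcs.sort()

    touched = [a[:2] for a in arcs] + ([composite] if composite else [])
    boundary = any(s == 0 or e == n - 1 for s, e in touched)
    return KnotRecord(
        frame_index=frame_index,
        isolated_arcs=arcs,
        composite_arc=composite,
        boundary_contact=boundary,
    )


# ---------------------------------------------------------------------------
# chirality


def writhe(poly: ClosedPolygon) -> float:
    """Space writhe of a closed polygon via the exact Gauss double sum
    over segment pairs (pairwise solid-angle contributions)."""
    p = poly.vertices
    m = len(p)
    q = np.roll(p, -1, axis=0)
    total = 0.0
    for i in range(m - 1):
        p1, p2 = p[i], q[i]
        j0 = i + 2
        j1 = m if i > 0 else m - 1  # skip segments sharing a vertex
        for j in range(j0, j1):
            p3, p4 = p[j], q[j]
            total += _gauss_pair(p1, p2, p3, p4)
    return 2.0 * total


def _gauss_pair(p1, p2, p3, p4) -> float:
    r12 = p2 - p1
    r34 = p4 - p3
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)
    norms = [np.linalg.norm(v) for v in (n1, n2, n3, n4)]
    if min(norms) < 1e-14:
        return 0.0
    n1, n2, n3, n4 = (v / nv for v, nv in zip((n1, n2, n3, n4), norms))
    omega = (
        np.arcsin(np.clip(n1 @ n2, -1.0, 1.0))
        + np.arcsin(np.clip(n2 @ n3, -1.0, 1.0))
        + np.arcsin(np.clip(n3 @ n4, -1.0, 1.0))
        + np.arcsin(np.clip(n4 @ n1, -1.0, 1.0))
    )
    sign = np.sign(np.cross(r34, r12) @ r13)
    return omega * sign / (4.0 * np.pi)


def handedness(chain, arc: Tuple[int, int], seed: int = 0) -> int:
    """Handedness of a trefoil arc: +1 right-handed, -1 left-handed.

    The MIC-closed arc must classify as a trefoil; the sign is that of
    the space writhe of the closed curve, which for trefoils equals the
    sign of the summed signed crossings of a reduced diagram.
    """
    pos = _positions(chain)
    s, e = arc
    sub = pos[s : e + 1]
    poly = close_arc_mic(sub)
    lab = classify_topology(*alexander_determinants(poly, seed=seed))
    if lab.label != "trefoil":
        raise WrongTopologyError(
            f"arc ({s}, {e}) closes to {lab.label}, not a trefoil"
        )
    w = writhe(poly)
    return 1 if w > 0 else -1
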