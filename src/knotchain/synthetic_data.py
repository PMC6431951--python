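"""Generators for every input the pipeline needs.

Chain fixtures are built geometrically: a closed (2,3)-torus trefoil is
discretized at equal arc length, cut at its outermost bond, and pulled
out along the local outward direction into a "lollipop" template whose
two tips sit on the stretching axis. Splicing a template into a
straight tethered backbone therefore never threads a strand through a
loop, so the topology of the assembled chain is known by construction
(and is re-verified by the analysis oracles in the tests).

Also here: the uniform microstate sampler of the two-sliding-segment
entropy model, surrogate |D| trajectories drawn from a target free
energy, and a capped-step zero-temperature minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .errors import DegenerateGeometryError, KnotchainError
from .free_energy import FreeEnergyProfile
from .model_core import Conformation, ModelParams, total_energy, forces
from .observables import OrderParamSeries

__all__ = [
    "KnotSpec",
    "make_torus_trefoil",
    "build_two_knot_chain",
    "sliding_segment_mc",
    "surrogate_knot_trajectory",
    "relax_minimize",
]


@dataclass
class KnotSpec:
    """Where and how to tie one trefoil into the chain.

    ``template_beads`` counts every bead of the spliced template (loop
    plus the two straight stalks that connect it to the backbone).
    """

    handedness: int = 1
    center_bead: int = 50
    template_beads: int = 24
    scale: float = 1.0
    knot_type: str = "trefoil"
    stalk_beads: int = 3

    def __post_init__(self) -> None:
        if self.handedness not in (+1, -1):
            raise ValueError("handedness must be +1 or -1")
        if self.knot_type != "trefoil":
            raise ValueError("only trefoil templates are supported")
        if self.template_beads - 2 * self.stalk_beads < 12:
            raise ValueError("template too small for a self-avoiding trefoil loop")


def _torus_trefoil_curve(t: np.ndarray) -> np.ndarray:
    """(2,3)-torus curve; this parameterization is left-handed
    (space writhe ~ -3.35)."""
    x = np.sin(t) + 2.0 * np.sin(2.0 * t)
    y = np.cos(t) - 2.0 * np.cos(2.0 * t)
    z = -np.sin(3.0 * t)
    return np.stack([x, y, z], axis=1)


def make_torus_trefoil(
    n_beads: int,
    handedness: int = 1,
    scale: float = 1.0,
    sigma: float = 1.0,
    min_clearance: float = 0.75,
) -> np.ndarray:
    """Closed trefoil polygon with n_beads vertices and equal bond
    lengths equal to ``scale``.

    ``handedness`` +1 gives a right-handed knot (positive writhe), -1
    its mirror image. Raises when the scaled curve is not self-avoiding
    at bead diameter ``sigma`` (non-adjacent vertices closer than
    ``min_clearance * sigma``).
    """
    if n_beads < 12:
        raise ValueError("need at least 12 beads for a polygonal trefoil")
    fine = _torus_trefoil_curve(np.linspace(0.0, 2.0 * np.pi, 20000, endpoint=False))
    seg = np.linalg.norm(np.diff(np.vstack([fine, fine[:1]]), axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    targets = np.linspace(0.0, total, n_beads, endpoint=False)
    idx = np.searchsorted(arclen, targets, side="right") - 1
    frac = (targets - arclen[idx]) / seg[idx]
    ring = np.vstack([fine, fine[:1]])
    pts = ring[idx] + frac[:, None] * (ring[idx + 1] - ring[idx])

    bond = np.mean(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1))
    pts = pts * (scale / bond)
    if handedness == 1:
        pts = pts * np.array([1.0, 1.0, -1.0])  # mirror the left-handed base
    elif handedness != -1:
        raise ValueError("handedness must be +1 or -1")

    # self-avoidance at bead diameter sigma
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    n = n_beads
    ii, jj = np.triu_indices(n, k=2)
    nonadj = ~((ii == 0) & (jj == n - 1))
    dmin = float(d[ii[nonadj], jj[nonadj]].min())
    if dmin < min_clearance * sigma:
        raise KnotchainError(
            f"scale {scale} too small for self-avoidance: closest "
            f"non-adjacent beads at {dmin:.3f} sigma"
        )
    return pts


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(a @ p) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1.0 - c) / float(v @ v))


def _lollipop_template(spec: KnotSpec, sigma: float = 1.0) -> np.ndarray:
    """Open trefoil template: loop cut at its outermost bond, both cut
    ends extended by straight stalks along the local outward direction.

    Returned in a canonical frame: the stalk tips are the first and
    last beads, both near the z = 0 plane, with the tip-to-tip vector
    along +x and the knot body at negative z.
    """
    n_loop = spec.template_beads - 2 * spec.stalk_beads
    loop = make_torus_trefoil(n_loop, spec.handedness, spec.scale, sigma=sigma)
    centroid = loop.mean(axis=0)

    mids = 0.5 * (loop + np.roll(loop, -1, axis=0))
    cut = int(np.argmax(np.linalg.norm(mids - centroid, axis=1)))
    outward = mids[cut] - centroid
    outward /= np.linalg.norm(outward)

    # open the loop at bond (cut, cut+1): path runs cut+1 ... cut
    path = np.roll(loop, -(cut + 1), axis=0)
    v_start, v_end = path[0], path[-1]

    # stalk rays must clear the rest of the loop before we pull out
    for v in (v_start, v_end):
        body = path[2:-2]
        w = body - v
        along = w @ outward
        perp = np.linalg.norm(w - np.outer(along, outward), axis=1)
        ahead = along > 0.5 * spec.scale
        if np.any(ahead & (perp < 0.8 * sigma)):
            raise DegenerateGeometryError(
                "stalk ray threads the knot loop; change template size"
            )

    stalk = spec.stalk_beads
    pre = [v_start + (stalk - j) * spec.scale * outward for j in range(stalk)]
    post = [v_end + (j + 1) * spec.scale * outward for j in range(stalk)]
    pts = np.vstack([pre, path, post])

    # canonical frame: outward -> +z, tips first/last
    rot = _rotation_to(outward, np.array([0.0, 0.0, 1.0]))
    pts = pts @ rot.T
    tip_vec = pts[-1] - pts[0]
    horiz = np.array([tip_vec[0], tip_vec[1], 0.0])
    if np.linalg.norm(horiz) > 1e-9:
        rot2 = _rotation_to(horiz / np.linalg.norm(horiz), np.array([1.0, 0.0, 0.0]))
        pts = pts @ rot2.T
    pts = pts - pts[0]
    return pts


def _splice(path: np.ndarray, template: np.ndarray, bond_index: int,
            direction: np.ndarray, offset: float) -> np.ndarray:
    """Insert *template* (canonical frame) between beads bond_index and
    bond_index + 1 of *path*, dangling along *direction* (the canonical
    -z of the template maps onto it).

    The template tips straddle the midpoint of the replaced bond,
    pushed ``offset`` outward along *direction*, so neither tip can
    coincide with a path vertex.
    """
    a = path[bond_index]
    b = path[bond_index + 1]
    tpl = template @ _rotation_to(np.array([0.0, 0.0, -1.0]), direction).T
    tip_vec = tpl[-1] - tpl[0]
    bond_dir = b - a
    # align the tip separation with the replaced bond as far as possible
    proj = bond_dir - (bond_dir @ direction) * direction
    tv_proj = tip_vec - (tip_vec @ direction) * direction
    if np.linalg.norm(proj) > 1e-9 and np.linalg.norm(tv_proj) > 1e-9:
        tpl = tpl @ _rotation_about(direction, tv_proj, proj).T
    tip_vec = tpl[-1] - tpl[0]
    mid = 0.5 * (a + b) + offset * direction
    tpl = tpl - tpl[0] + (mid - 0.5 * tip_vec)
    return np.vstack([path[: bond_index + 1], tpl, path[bond_index + 1 :]])


def _rotation_about(axis: np.ndarray, frm: np.ndarray, to: np.ndarray) -> np.ndarray:
    """Rotation about *axis* taking the direction of *frm* (projected
    perpendicular to axis) onto that of *to*."""
    axis = axis / np.linalg.norm(axis)
    f = frm - (frm @ axis) * axis
    t = to - (to @ axis) * axis
    f /= np.linalg.norm(f)
    t /= np.linalg.norm(t)
    cosang = float(np.clip(f @ t, -1.0, 1.0))
    sinang = float(np.cross(f, t) @ axis)
    ang = np.arctan2(sinang, cosang)
    c, s = np.cos(ang), np.sin(ang)
    vx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) * c + s * vx + (1 - c) * np.outer(axis, axis)


def build_two_knot_chain(
    params: ModelParams,
    spec1: KnotSpec,
    spec2: KnotSpec,
    intertwined: bool = False,
) -> Conformation:
    """Stretched chain between the walls carrying two trefoil templates.

    Separated: both templates are spliced into the straight backbone at
    their requested centers. Intertwined: ``spec2`` is spliced into the
    middle of ``spec1``'s loop so that its arc is nested inside the
    hosting knot's arc along the chain.

    End beads sit exactly at (0, 0, 0) and (L, 0, 0). Bond lengths stay
    below R0; minor steric overlaps are left for a short
    zero-temperature relaxation (:func:`relax_minimize`).
    """
    n_total = params.N
    length = params.L_wall
    tpl1 = _lollipop_template(spec1, sigma=params.sigma)
    tpl2 = _lollipop_template(spec2, sigma=params.sigma)

    if intertwined:
        inserts = [(spec1, _nest_templates(tpl1, tpl2))]
    else:
        if spec1.center_bead > spec2.center_bead:
            spec1, spec2 = spec2, spec1
            tpl1, tpl2 = tpl2, tpl1
        inserts = [(spec1, tpl1), (spec2, tpl2)]

    n_template = sum(len(t) for _, t in inserts)
    n_backbone = n_total - n_template
    if n_backbone < 2 + 2 * len(inserts):
        raise ValueError("templates leave too few backbone beads")

    advance = sum(float(t[-1, 0] - t[0, 0]) for _, t in inserts)
    n_gap_bonds = 2 * len(inserts)
    n_straight = n_backbone - 1 - len(inserts)
    b_s = (length - advance) / (n_straight + n_gap_bonds)
    if not (0.2 * params.sigma < b_s < 0.98 * params.R0):
        raise ValueError(
            f"backbone bond {b_s:.3f} infeasible for N={n_total}, L={length}, "
            f"templates of {n_template} beads"
        )

    # desired start bead of each insert along the final chain
    starts = [max(5, spec.center_bead - len(tpl) // 2) for spec, tpl in inserts]
    prev_end = 0
    for start, (_, tpl) in zip(starts, inserts):
        if start < prev_end + 2:
            raise ValueError("knot templates overlap along the chain")
        prev_end = start + len(tpl)
    if prev_end > n_total - 6:
        raise ValueError("knot centers too close to the far wall")

    beads: List[np.ndarray] = [np.array([0.0, 0.0, 0.0])]
    x = 0.0
    insert_iter = iter(zip(starts, inserts))
    nxt = next(insert_iter, None)
    while len(beads) < n_total:
        if nxt is not None and len(beads) == nxt[0]:
            _, (spec, tpl) = nxt
            placed = tpl - tpl[0] + np.array([x + b_s, 0.0, 0.0])
            beads.extend(placed)
            x = float(placed[-1, 0])
            nxt = next(insert_iter, None)
            continue
        x += b_s
        beads.append(np.array([x, 0.0, 0.0]))
    pos = np.array(beads[:n_total])

    # the bond count solved for b_s lands the last bead on the far wall
    # up to float roundoff; pin it exactly
    if abs(length - pos[-1, 0]) > 0.3 * b_s:
        raise ValueError("assembly failed to reach the far wall")
    pos[-1] = np.array([length, 0.0, 0.0])
    return Conformation(pos)


def _nest_templates(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Splice *inner* into the middle of *outer*'s loop, dangling
    outward, producing a combined open template (intertwined state)."""
    n = len(outer)
    # loop body of the outer template (skip stalks); choose the bond
    # whose midpoint is farthest from the tip-to-tip axis
    lo, hi = n // 4, 3 * n // 4
    mids = 0.5 * (outer[lo : hi - 1] + outer[lo + 1 : hi])
    axis_pt = outer[0]
    axis_dir = np.array([1.0, 0.0, 0.0])
    w = mids - axis_pt
    perp = w - np.outer(w @ axis_dir, axis_dir)
    k = lo + int(np.argmax(np.linalg.norm(perp, axis=1)))
    centroid = outer.mean(axis=0)
    direction = 0.5 * (outer[k] + outer[k + 1]) - centroid
    direction /= np.linalg.norm(direction)
    offset = 0.8 * np.linalg.norm(outer[k + 1] - outer[k])
    return _splice(outer, inner, k, direction, offset)


# ---------------------------------------------------------------------------
# statistical surrogates


def sliding_segment_mc(
    N: int,
    lk: int,
    n_samples: int,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Center separations |D| of two indistinguishable segments of
    length lk sliding on an N-site line, sampled uniformly over the
    unordered microstates.

    Uses the classic trick for uniform unordered pairs with
    replacement: draw a in [0, M), b in [0, M]; b == M maps to the
    diagonal pair (a, a). ``exhaustive`` returns every microstate's |D|
    exactly once instead (deterministic, small N only).
    """
    if not lk < N:
        raise ValueError("need lk < N")
    m = N - lk + 1  # number of segment start positions
    if exhaustive:
        out = []
        for a in range(m):
            for b in range(a, m):
                out.append(b - a)
        return np.asarray(out)
    rng = np.random.default_rng(seed)
    a = rng.integers(0, m, size=n_samples)
    b = rng.integers(0, m + 1, size=n_samples)
    b = np.where(b == m, a, b)
    return np.abs(b - a)


def surrogate_knot_trajectory(
    F_target,
    n_frames: int,
    seed: int = 0,
    kBT: float = 1.0,
) -> List[OrderParamSeries]:
    """Surrogate |D| series with frames distributed as exp(-F/kBT).

    ``F_target`` is a FreeEnergyProfile or a (D values, F values) pair;
    non-finite F bins get zero weight. Feeding the output to
    estimate_profile recovers F_target up to an additive constant.
    """
    if isinstance(F_target, FreeEnergyProfile):
        d, f = F_target.bin_centers, F_target.F
    else:
        d, f = np.asarray(F_target[0], float), np.asarray(F_target[1], float)
    w = np.where(np.isfinite(f), np.exp(-(f - np.nanmin(f)) / kBT), 0.0)
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    samples = rng.choice(d, size=n_frames, p=p)
    return [
        OrderParamSeries(frame_index=i, D_abs=float(v), state="separated")
        for i, v in enumerate(samples)
    ]


def relax_minimize(
    conf: Conformation,
    params: ModelParams,
    n_steps: int = 1000,
    max_disp: float = 0.05,
    step0: float = 1.0e-4,
) -> Conformation:
    """Zero-temperature capped-step steepest descent.

    Displacements are limited to ``max_disp`` per bead per step, which
    together with the WCA core keeps strands from crossing; steps that
    would raise the energy (or overstretch a bond) are rejected and the
    step size halved. The energy never increases across accepted steps.
    The tethered termini do not move.
    """
    pos = conf.positions.copy()
    alpha = step0

    def _energy(p):
        return total_energy(Conformation(p), params).total

    e_cur = _energy(pos)
    for _ in range(n_steps):
        f = forces(Conformation(pos), params)
        f[0] = 0.0
        f[-1] = 0.0
        disp = alpha * f
        mag = np.linalg.norm(disp, axis=1)
        big = mag > max_disp
        if big.any():
            disp[big] *= (max_disp / mag[big])[:, None]
        trial = pos + disp
        try:
            e_new = _energy(trial)
        except KnotchainError:
            e_new = np.inf
        if np.isfinite(e_new) and e_new <= e_cur:
            pos = trial
            e_cur = e_new
            alpha = min(alpha * 1.2, 1.0)
        else:
            alpha *= 0.5
            if alpha < 1e-12:
                break
    return Conformation(pos)
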