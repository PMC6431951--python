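"""Collective order parameters: knot separation |D| and the relative
orientation angles theta and theta_perp.

The stretching axis is X by package-wide convention; theta_perp lives
in the YZ plane perpendicular to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .knot_analysis import KnotRecord
from .model_core import Conformation

__all__ = [
    "KnotDirector",
    "OrderParamSeries",
    "knot_center",
    "separation_D",
    "orientation_director",
    "theta",
    "theta_perp",
    "order_params_for_frame",
]


@dataclass
class KnotDirector:
    """Unit normal of the idealized knot loop disc."""

    U: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (3,):
            raise ValueError("director must be a 3-vector")
        n = np.linalg.norm(self.U)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("director must be a unit vector")


@dataclass
class OrderParamSeries:
    """Per-frame order parameters.

    ``theta``/``theta_perp`` are NaN when a director (or its YZ
    projection) is undefined for that frame; such frames are excluded
    from angle statistics rather than imputed.
    """

    frame_index: int
    D_abs: float
    state: str  # "separated" | "intertwined"
    theta: float = float("nan")
    theta_perp: float = float("nan")
    which_nested: Optional[int] = None


def knot_center(arc: Tuple[int, int]) -> float:
    """Center bead index c = (s + e) / 2 of an inclusive arc."""
    s, e = arc[0], arc[1]
    return 0.5 * (s + e)


def separation_D(record: KnotRecord) -> Tuple[float, str]:
    """|D| and the separated/intertwined state flag for one frame.

    Separated (two isolated components): |c1 - c2|. Intertwined (one
    isolated = the nested knot): distance from the nested center to the
    center of the whole composite arc.
    """
    n_iso = record.n_isolated
    if n_iso == 2:
        c1 = knot_center(record.isolated_arcs[0][:2])
        c2 = knot_center(record.isolated_arcs[1][:2])
        return abs(c1 - c2), "separated"
    if n_iso == 1:
        if record.composite_arc is None:
            raise ValueError(
                "intertwined frame without a composite arc; cannot form |D|"
            )
        c_nest = knot_center(record.isolated_arcs[0][:2])
        c_comp = knot_center(record.composite_arc)
        return abs(c_nest - c_comp), "intertwined"
    raise ValueError(f"expected 1 or 2 isolated components, got {n_iso}")


def _director_from_bond_pairs(bonds: np.ndarray, pair_idx: Sequence[int]):
    total = np.zeros(3)
    for j in pair_idx:
        total += np.cross(bonds[j], bonds[j + 1])
    norm = np.linalg.norm(total)
    if norm < 1e-10:
        return None
    return KnotDirector(total / norm)


def orientation_director(
    chain: Conformation | np.ndarray,
    arc: Tuple[int, int],
    exclude_arc: Optional[Tuple[int, int]] = None,
) -> Optional[KnotDirector]:
    """Loop normal of an arc: normalized sum of cross products of
    consecutive bond vectors over the arc (right-hand rule along the
    traversal direction).

    ``exclude_arc`` removes a nested sub-arc's bonds from the sum; this
    is how the outer director of an intertwined composite is computed
    (only bond pairs fully complementary to the nested knot
    contribute). Returns None when the cross-product sum vanishes.
    """
    pos = chain.positions if isinstance(chain, Conformation) else np.asarray(chain)
    s, e = arc
    if e - s < 3:
        raise ValueError("arc needs at least 3 bonds for a director")
    bonds = np.diff(pos, axis=0)
    pairs = range(s, e - 1)  # bond pairs (j, j+1) inside the arc
    if exclude_arc is not None:
        xs, xe = exclude_arc
        # keep pairs whose both bonds lie outside the excluded bead range
        pairs = [
            j for j in pairs if (j + 2 <= xs or j >= xe)
        ]
    else:
        pairs = list(pairs)
    return _director_from_bond_pairs(bonds, pairs)


def theta(U1: KnotDirector, U2: KnotDirector) -> float:
    """Cone aperture between two directors, arccos(U1.U2) in [0, pi]."""
    return float(np.arccos(np.clip(U1.U @ U2.U, -1.0, 1.0)))


def theta_perp(U1: KnotDirector, U2: KnotDirector) -> float:
    """Signed angle between the YZ-plane projections of the directors.

    Magnitude from atan2(|V1 x V2|, V1.V2) on the normalized
    projections; the sign is that of the X component of U1 x U2.
    Returns NaN if either projection vanishes.
    """
    v1 = U1.U[1:]
    v2 = U2.U[1:]
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        return float("nan")
    v1 = v1 / n1
    v2 = v2 / n2
    crossmag = abs(v1[0] * v2[1] - v1[1] * v2[0])
    mag = float(np.arctan2(crossmag, v1 @ v2))
    sx = np.cross(U1.U, U2.U)[0]
    sign = 1.0 if sx > 0 else (-1.0 if sx < 0 else 1.0)
    return sign * mag


def order_params_for_frame(
    chain: Conformation | np.ndarray,
    record: KnotRecord,
) -> OrderParamSeries:
    """Assemble |D|, theta, theta_perp for one localized frame.

    For separated frames the two directors are those of the two
    isolated arcs (chain order). For intertwined frames U1 belongs to
    the nested knot and U2 to the composite-arc region complementary
    to it.
    """
    d_abs, state = separation_D(record)
    out = OrderParamSeries(frame_index=record.frame_index, D_abs=d_abs, state=state)
    if state == "separated":
        u1 = orientation_director(chain, record.isolated_arcs[0][:2])
        u2 = orientation_director(chain, record.isolated_arcs[1][:2])
    else:
        nested = record.isolated_arcs[0][:2]
        u1 = orientation_director(chain, nested)
        u2 = orientation_director(chain, record.composite_arc, exclude_arc=nested)
        out.which_nested = record.isolated_arcs[0][2] or None
    if u1 is not None and u2 is not None:
        out.theta = theta(u1, u2)
        out.theta_perp = theta_perp(u1, u2)
    return out
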