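"""Free-energy profiles over the knot separation |D|, the exact
two-sliding-segment entropy model, and the elastic knot-size model.

The entropy model maps the chain onto a line of N sites along which two
indistinguishable segments of length lk slide freely; its microstate
fraction is exact and is used to subtract the purely entropic part of
F(|D|). The elastic model balances the bending energy stored in a knot
(loop of radius R plus a braid of extent ~2R) against a quadratic
tension term, giving a closed-form equilibrium knot size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FreeEnergyProfile",
    "ProfileFeatures",
    "ElasticModel",
    "estimate_profile",
    "microstate_fraction",
    "entropy_S",
    "subtract_entropy",
    "extract_features",
    "knot_bending_energy",
    "tension_energy",
    "elastic_total_energy",
    "equilibrium_knot_size",
    "fit_Q",
]

#: geometric constant 2 (pi + 1)^2 of the loop-plus-braid bending model
_BEND_COEFF = 2.0 * (np.pi + 1.0) ** 2

#: default plateau window, in fractions of the chain length
PLATEAU_WINDOW = (0.35, 0.55)


@dataclass
class FreeEnergyProfile:
    """Binned F(|D|) in kBT, defined up to an additive constant.

    Bins with zero counts carry NaN in ``F`` (masked, never -inf).
    ``F_corrected`` is filled by :func:`subtract_entropy`.
    """

    bin_centers: np.ndarray
    F: np.ndarray
    counts: np.ndarray
    F_corrected: Optional[np.ndarray] = None
    kBT: float = 1.0

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass
class ProfileFeatures:
    """Barrier height above the entropic plateau (eps_b), depth of the
    |D| = 0 minimum below the barrier (eps_d), and the interaction
    onset distance Dint; NaN fields mean 'not resolved'."""

    eps_b: float = float("nan")
    eps_d: float = float("nan")
    D_int: float = float("nan")
    plateau: float = float("nan")
    plateau_sd: float = float("nan")


@dataclass
class ElasticModel:
    """Tension coefficient Q (energy per bead^2) and bond length."""

    Q: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError("Q must be > 0")


def _extract_D(series) -> np.ndarray:
    vals = []
    for item in series:
        vals.append(item.D_abs if hasattr(item, "D_abs") else float(item))
    return np.asarray(vals, dtype=float)


def estimate_profile(
    series: Sequence,
    kBT: float = 1.0,
    bin_width: float = 2.0,
    N: Optional[int] = None,
    plateau_window: Tuple[float, float] = PLATEAU_WINDOW,
) -> FreeEnergyProfile:
    """F(|D|) = -kBT ln p(|D|) from pooled samples.

    ``series`` may hold OrderParamSeries records or bare |D| values.
    The additive constant is fixed by zeroing the mean over the plateau
    window [0.35 N, 0.55 N] when ``N`` is given, otherwise by setting
    the minimum resolved F to zero.
    """
    d = _extract_D(series)
    if d.size == 0:
        raise ValueError("empty series")
    hi = float(d.max()) + bin_width
    edges = np.arange(-0.5 * bin_width, hi + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum() / bin_width
    with np.errstate(divide="ignore"):
        f = np.where(counts > 0, -kBT * np.log(np.where(counts > 0, p, 1.0)), np.nan)
    if N is not None:
        lo, hi_w = plateau_window[0] * N, plateau_window[1] * N
        window = (centers >= lo) & (centers <= hi_w) & np.isfinite(f)
        if window.any():
            f = f - np.nanmean(f[window])
        else:
            f = f - np.nanmin(f)
    else:
        f = f - np.nanmin(f)
    return FreeEnergyProfile(bin_centers=centers, F=f, counts=counts, kBT=kBT)


def microstate_fraction(D: int, N: int, lk: int):
    """Fraction of sliding-segment microstates with center separation D:

        omega = 2 (N - lk + 1 - D) / [(N - lk + 2)(N - lk + 1)]

    Exact for integer D in [0, N - lk + 1]; normalized to 1 over that
    range. Raises on out-of-range D.
    """
    m = N - lk + 1
    if m < 1:
        raise ValueError("need lk <= N")
    d = np.asarray(D)
    if np.any(d < 0) or np.any(d > m):
        raise ValueError(f"D must lie in [0, {m}]")
    out = 2.0 * (m - d) / ((m + 1.0) * m)
    return float(out) if out.ndim == 0 else out


def entropy_S(D, N: int, lk: int):
    """Sliding-segment entropy kB ln omega(D); -inf where omega = 0
    (callers mask such bins rather than propagate them)."""
    w = np.asarray(microstate_fraction(D, N, lk), dtype=float)
    with np.errstate(divide="ignore"):
        s = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
    return float(s) if s.ndim == 0 else s


def subtract_entropy(
    profile: FreeEnergyProfile, N: int, lk: float
) -> FreeEnergyProfile:
    """Add T S(|D|) to F, cancelling the sliding-segment entropy.

    ``lk`` is the measured mean separated-knot size; the (linear-in-D)
    microstate formula is evaluated at the real-valued bin centers. On
    data generated by the pure sliding-segment model the corrected
    profile is flat.
    """
    m = N - int(round(lk)) + 1
    d = profile.bin_centers
    w = np.full_like(d, np.nan)
    ok = (d >= 0) & (d < m)
    w[ok] = 2.0 * (m - d[ok]) / ((m + 1.0) * m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = profile.kBT * np.log(w)
    corrected = profile.F + ts
    return FreeEnergyProfile(
        bin_centers=profile.bin_centers.copy(),
        F=profile.F.copy(),
        counts=profile.counts.copy(),
        F_corrected=corrected,
        kBT=profile.kBT,
    )


def corrected_slope_ci(
    profile: FreeEnergyProfile, N: int, alpha: float = 0.05
) -> Tuple[float, float, float]:
    """Fitted slope of F_corrected vs |D| over the interior of the
    profile, with its (1 - alpha) confidence interval."""
    if profile.F_corrected is None:
        raise ValueError("run subtract_entropy first")
    d = profile.bin_centers
    y = profile.F_corrected
    # low-count bins bias -ln(counts) and are excluded from the fit
    ok = (
        np.isfinite(y)
        & (d > 0)
        & (d < 0.9 * (N - 1))
        & (profile.counts >= 25)
    )
    if ok.sum() < 3:
        raise ValueError("too few resolved bins for a slope fit")
    res = stats.linregress(d[ok], y[ok])
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, int(ok.sum()) - 2)
    half = tcrit * res.stderr
    return float(res.slope), float(res.slope - half), float(res.slope + half)


def extract_features(
    profile: FreeEnergyProfile,
    N: int,
    threshold: Optional[float] = None,
    plateau_window: Tuple[float, float] = PLATEAU_WINDOW,
) -> ProfileFeatures:
    """Locate the barrier, the |D| = 0 minimum, and the interaction
    onset on an F(|D|) profile.

    The plateau level (and its standard deviation) is measured over the
    plateau window; the onset Dint is found by scanning |D| downward
    from N/2: it is the largest |D| at which F exceeds plateau +
    threshold (default threshold: two plateau standard deviations).
    eps_b is the barrier maximum above the
    plateau for |D| below the onset; eps_d is the drop from the barrier
    to the |D| = 0 bin. Unresolvable features come back NaN.
    """
    d = profile.bin_centers
    f = profile.F
    ok = np.isfinite(f)
    out = ProfileFeatures()

    lo, hi = plateau_window[0] * N, plateau_window[1] * N
    window = ok & (d >= lo) & (d <= hi)
    if not window.any():
        return out
    plateau = float(np.mean(f[window]))
    plateau_sd = float(np.std(f[window]))
    out.plateau = plateau
    out.plateau_sd = plateau_sd
    thr = threshold if threshold is not None else 2.0 * plateau_sd

    half = 0.5 * N
    idx = np.where(ok & (d <= half))[0]
    if idx.size == 0:
        return out
    # scan downward from N/2: onset = largest |D| whose F exceeds the
    # detection threshold above the plateau
    onset = None
    for k in range(len(idx) - 1, -1, -1):
        i = idx[k]
        if f[i] > plateau + thr:
            onset = i
            break
    if onset is None:
        return out  # no resolved rise: no barrier features
    out.D_int = float(d[onset])

    inner = ok & (d <= d[onset])
    if not inner.any():
        return out
    barrier_val = float(np.max(f[inner]))
    barrier_idx = int(np.where(inner)[0][np.argmax(f[inner])])
    out.eps_b = barrier_val - plateau

    zero_bin = int(np.argmin(np.abs(d)))
    if (
        np.isfinite(f[zero_bin])
        and d[zero_bin] < d[barrier_idx]
        and f[zero_bin] < barrier_val
    ):
        out.eps_d = barrier_val - float(f[zero_bin])
    return out


# ---------------------------------------------------------------------------
# elastic knot-size model


def knot_bending_energy(n: float, kappa_b: float, sigma: float = 1.0) -> float:
    """Bending energy of a knot of n beads modeled as a loop of radius
    R plus a braid of extent ~2R: 2 (pi + 1)^2 kappa_b / (sigma n)."""
    if n <= 0:
        raise ValueError("knot size must be > 0")
    return _BEND_COEFF * kappa_b / (sigma * n)


def tension_energy(n: float, Q: float) -> float:
    """Quadratic tension contribution Q n^2 / 2."""
    return 0.5 * Q * n**2


def elastic_total_energy(
    n1: float, n2: float, kappa_b: float, Q: float, sigma: float = 1.0
) -> float:
    """Total elastic free energy of two independent, equivalent knots."""
    return sum(
        knot_bending_energy(n, kappa_b, sigma) + tension_energy(n, Q)
        for n in (n1, n2)
    )


def equilibrium_knot_size(kappa_b: float, Q: float, sigma: float = 1.0) -> float:
    """Closed-form argmin of the per-knot elastic free energy:

        n* = (2 (pi + 1)^2 sigma kappa_b / Q)^(1/3)
    """
    if Q <= 0:
        raise ValueError("Q must be > 0")
    return (_BEND_COEFF * sigma * kappa_b / Q) ** (1.0 / 3.0)


def fit_Q(
    sizes: Sequence[Tuple[float, float]], sigma: float = 1.0
) -> float:
    """Tension coefficient from measured (kappa_b, knot size) pairs.

    A single calibration point inverts the minimum condition exactly:
    Q = 2 (pi + 1)^2 sigma kappa_b / n^3. Several points are combined
    by least squares on the predicted sizes.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("need at least one calibration point")
    if any(n <= 0 for _, n in sizes):
        raise ValueError("knot sizes must be > 0")
    point_estimates = [_BEND_COEFF * sigma * kb / n**3 for kb, n in sizes]
    if len(sizes) == 1:
        return float(point_estimates[0])

    kbs = np.array([kb for kb, _ in sizes])
    ns = np.array([n for _, n in sizes])

    def residuals(logq):
        return equilibrium_knot_size(kbs, np.exp(logq), sigma) - ns

    sol = optimize.least_squares(residuals, x0=np.log(np.mean(point_estimates)))
    return float(np.exp(sol.x[0]))
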