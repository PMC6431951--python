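from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from knotchain.free_energy import (
    corrected_slope_ci,
    elastic_total_energy,
    entropy_S,
    equilibrium_knot_size,
    estimate_profile,
    extract_features,
    fit_Q,
    knot_bending_energy,
    microstate_fraction,
    subtract_entropy,
    tension_energy,
)
from knotchain.synthetic_data import sliding_segment_mc, surrogate_knot_trajectory


def enumerate_pair_separations(N, lk):
    """Brute-force oracle: all unordered placements of two length-lk
    segments on an N-site line (overlap allowed), keyed by center
    separation."""
    m = N - lk + 1
    counts = {}
    for a in range(m):
        for b in range(a, m):
            counts[b - a] = counts.get(b - a, 0) + 1
    total = sum(counts.values())
    return counts, total


class TestMicrostateFraction:
    def test_normalization_exact(self):
        for N, lk in [(10, 3), (50, 7), (200, 36), (200, 3)]:
            m = N - lk + 1
            # integer identity: sum_d 2(m - d) = m (m + 1), so the
            # fractions sum to exactly 1
            assert sum(2 * (m - d) for d in range(m + 1)) == m * (m + 1)
            exact = sum(
                Fraction(2 * (m - d), (m + 1) * m) for d in range(m + 1)
            )
            assert exact == 1
            assert sum(
                microstate_fraction(d, N, lk) for d in range(m + 1)
            ) == pytest.approx(1.0, abs=1e-12)

    def test_example_n10_lk3(self):
        # enumeration oracle gives 8 of 36 placements at D = 0
        counts, total = enumerate_pair_separations(10, 3)
        assert Fraction(counts[0], total) == Fraction(2, 9)
        assert microstate_fraction(0, 10, 3) == pytest.approx(2.0 / 9.0)

    def test_no_room_at_max_separation(self):
        assert microstate_fraction(8, 10, 3) == 0.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            microstate_fraction(9, 10, 3)
        with pytest.raises(ValueError):
            microstate_fraction(-1, 10, 3)

    @pytest.mark.parametrize("N", [8, 15, 23, 30])
    def test_matches_enumeration(self, N):
        for lk in range(3, N):
            counts, total = enumerate_pair_separations(N, lk)
            m = N - lk + 1
            for d in range(m + 1):
                expect = counts.get(d, 0) / total
                assert microstate_fraction(d, N, lk) == pytest.approx(
                    expect, abs=1e-14
                )


class TestMicrostateProperties:
    @given(
        N=st.integers(min_value=5, max_value=300),
        lk=st.integers(min_value=3, max_value=299),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalized_and_monotone(self, N, lk):
        if lk >= N:
            lk = N - 1
        m = N - lk + 1
        w = microstate_fraction(np.arange(m + 1), N, lk)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(w) < 0)  # fewer placements at larger D
        assert w[-1] == 0.0

    @given(
        kb=st.floats(min_value=0.1, max_value=100.0),
        q=st.floats(min_value=1e-4, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_fit_q_inverts_equilibrium_size(self, kb, q):
        n = equilibrium_knot_size(kb, q)
        assert fit_Q([(kb, n)]) == pytest.approx(q, rel=1e-9)


class TestEntropy:
    def test_maximal_at_zero(self):
        s = [entropy_S(d, 10, 3) for d in range(8)]
        assert s[0] == max(s)
        assert all(np.diff(s) < 0)

    def test_differences_are_log_ratios(self):
        assert entropy_S(0, 10, 3) - entropy_S(4, 10, 3) == pytest.approx(
            np.log(8.0 / 4.0)
        )

    def test_zero_omega_masked(self):
        assert entropy_S(8, 10, 3) == -np.inf


class TestEstimateProfile:
    def test_uniform_samples_flat(self, rng):
        d = rng.uniform(0, 50, size=200_000)
        prof = estimate_profile(d, bin_width=2.0)
        ok = np.isfinite(prof.F)
        assert np.nanstd(prof.F[ok][1:-1]) < 0.05

    def test_two_bin_ratio(self):
        d = np.concatenate([np.full(2000, 1.0), np.full(1000, 3.0)])
        prof = estimate_profile(d, bin_width=2.0)
        ok = np.where(prof.counts > 0)[0]
        assert prof.F[ok[1]] - prof.F[ok[0]] == pytest.approx(np.log(2.0))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_profile([])

    def test_inverse_sampling_recovery(self):
        centers = np.arange(0.0, 60.0, 2.0)
        f0 = 0.002 * (centers - 30.0) ** 2  # gentle well
        series = surrogate_knot_trajectory((centers, f0), 100_000, seed=5)
        prof = estimate_profile(series, bin_width=2.0)
        common = np.isfinite(prof.F) & (prof.counts > 50)
        delta = prof.F[common] - np.interp(prof.bin_centers[common], centers, f0)
        rms = np.sqrt(np.mean((delta - delta.mean()) ** 2))
        assert rms < 0.1


class TestEntropySubtraction:
    def test_mc_flattening(self):
        N, lk = 100, 20
        d = sliding_segment_mc(N, lk, 100_000, seed=11)
        # integer order parameter: unit bins avoid within-bin averaging
        prof = estimate_profile(d.astype(float), bin_width=1.0)
        prof = subtract_entropy(prof, N, lk)
        slope, lo, hi = corrected_slope_ci(prof, N)
        assert lo <= 0.0 <= hi
        assert abs(slope) < 0.01

    def test_constant_shift(self):
        centers = np.arange(0.0, 40.0, 2.0)
        prof = estimate_profile(
            np.repeat(centers, 100), bin_width=2.0
        )
        corrected = subtract_entropy(prof, 100, 20)
        ok = np.isfinite(corrected.F_corrected)
        # F flat, so F_corrected = T S + const: strictly decreasing in D
        diffs = np.diff(corrected.F_corrected[ok])
        assert np.all(diffs < 0)


def synthetic_profile(N=100):
    """Noiseless profile with known features: plateau 0, onset at 45,
    barrier 1.5 at D = 30, minimum -2 at D = 0."""
    d = np.arange(0.0, 76.0)
    f = np.zeros_like(d)
    rise = (d >= 30) & (d <= 45)
    f[rise] = 1.5 * (45.0 - d[rise]) / 15.0
    f[rise & (d == 45.0)] = 0.05  # the onset bin itself pokes above
    inner = d < 30
    f[inner] = 1.5 - 3.5 * (30.0 - d[inner]) / 30.0
    counts = np.full_like(d, 1000, dtype=int)
    from knotchain.free_energy import FreeEnergyProfile

    return FreeEnergyProfile(bin_centers=d, F=f, counts=counts)


class TestExtractFeatures:
    def test_constructed_ground_truth(self):
        prof = synthetic_profile()
        feats = extract_features(prof, 100, threshold=0.02, plateau_window=(0.55, 0.75))
        assert feats.D_int == 45.0
        assert feats.eps_b == pytest.approx(1.5)
        assert feats.eps_d == pytest.approx(3.5)

    def test_no_minimum_low_stiffness(self):
        prof = synthetic_profile()
        # remove the minimum: monotonic decrease towards D=0 absent
        f = prof.F.copy()
        f[prof.bin_centers < 30] = 1.5  # plateau at barrier level inward
        prof.F = f
        feats = extract_features(prof, 100, threshold=0.02, plateau_window=(0.55, 0.75))
        assert np.isfinite(feats.eps_b)
        assert np.isnan(feats.eps_d)

    def test_threshold_robustness(self):
        prof = synthetic_profile()
        d0 = extract_features(prof, 100, threshold=0.02, plateau_window=(0.55, 0.75)).D_int
        for thr in (0.01, 0.03):
            di = extract_features(prof, 100, threshold=thr, plateau_window=(0.55, 0.75)).D_int
            assert abs(di - d0) < 2.0

    def test_flat_profile_no_features(self):
        from knotchain.free_energy import FreeEnergyProfile

        d = np.arange(0.0, 76.0)
        prof = FreeEnergyProfile(
            bin_centers=d, F=np.zeros_like(d), counts=np.full_like(d, 10, int)
        )
        feats = extract_features(prof, 100, threshold=0.5)
        assert np.isnan(feats.eps_b) and np.isnan(feats.D_int)


class TestElasticModel:
    def test_bending_energy_value(self):
        assert knot_bending_energy(36, 20.0) == pytest.approx(19.06, abs=0.01)

    def test_bending_scaling(self):
        assert knot_bending_energy(72, 20.0) == pytest.approx(
            0.5 * knot_bending_energy(36, 20.0)
        )
        assert knot_bending_energy(36, 0.0) == 0.0

    def test_bending_invalid_size(self):
        with pytest.raises(ValueError):
            knot_bending_energy(0, 20.0)

    def test_equilibrium_size_paper_point(self):
        n = equilibrium_knot_size(20.0, 0.015)
        assert n == pytest.approx(35.8, abs=0.1)
        assert round(n) == 36

    @pytest.mark.parametrize("kb", [2.5, 5.0, 10.0, 15.0, 20.0])
    def test_closed_form_matches_grid_search(self, kb):
        q = 0.015
        grid = np.arange(1, 201)
        energies = [
            elastic_total_energy(n, n, kb, q) for n in grid
        ]
        n_grid = grid[int(np.argmin(energies))]
        assert abs(equilibrium_knot_size(kb, q) - n_grid) <= 1.0

    def test_cube_root_scaling(self):
        assert equilibrium_knot_size(8 * 5.0, 0.015) == pytest.approx(
            2.0 * equilibrium_knot_size(5.0, 0.015)
        )

    def test_tension_energy(self):
        assert tension_energy(10.0, 0.015) == pytest.approx(0.75)


class TestFitQ:
    def test_paper_calibration(self):
        q = fit_Q([(20.0, 36.0)])
        assert q == pytest.approx(0.0147, abs=0.0002)
        assert float(f"{q:.2g}") == 0.015

    def test_round_trip(self):
        q = fit_Q([(20.0, 36.0)])
        assert equilibrium_knot_size(20.0, q) == pytest.approx(36.0, rel=1e-12)

    def test_multi_point_recovery(self):
        q_true = 0.0123
        pts = [(kb, equilibrium_knot_size(kb, q_true)) for kb in (2.5, 5, 10, 20)]
        assert fit_Q(pts) == pytest.approx(q_true, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_Q([])
        with pytest.raises(ValueError):
            fit_Q([(20.0, -5.0)])
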