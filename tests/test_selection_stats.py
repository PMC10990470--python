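"""Constituent statistics against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan._errors import DataError, ValidationError
from sweepscan.genotype_io import HaplotypeSet, make_site_table
from sweepscan.selection_stats import (
    EHHCurve,
    SiteStatTrack,
    delta_saf,
    ehh_at_core,
    fst_weir_cockerham,
    ihh,
    ihh_scan,
    standardize,
    xpehh,
)
from sweepscan.synthetic_data import SweepSimParams, simulate_sweep_panel


def wc_theta_oracle(n_dip_a, alt_a, n_dip_b, alt_b):
    """Independent scalar evaluation of the Weir–Cockerham a, b, c components
    (two populations, expected heterozygosity from allele counts)."""
    nal_a, nal_b = 2 * n_dip_a, 2 * n_dip_b
    p1, p2 = alt_a / nal_a, alt_b / nal_b
    h1 = 2 * p1 * (1 - p1) * nal_a / (nal_a - 1)
    h2 = 2 * p2 * (1 - p2) * nal_b / (nal_b - 1)
    n1, n2, r = n_dip_a, n_dip_b, 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def brute_force_ehh(H, core, side):
    """Identical-interval pair counting by explicit enumeration."""
    n, m = H.shape
    step = -1 if side == "left" else 1
    values = [1.0]
    j = core + step
    while 0 <= j < m:
        lo, hi = min(core, j), max(core, j)
        block = H[:, lo : hi + 1]
        pairs = 0
        for x in range(n):
            for y in range(x + 1, n):
                if np.array_equal(block[x], block[y]):
                    pairs += 1
        values.append(pairs / math.comb(n, 2))
        j += step
    return values


class TestFstWeirCockerham:
    def test_fixed_difference_is_exactly_one(self):
        track = fst_weir_cockerham(np.array([[40, 40]]), np.array([[40, 0]]))
        assert track.values[0] == 1.0

    def test_monomorphic_shared_allele_is_undefined(self):
        track = fst_weir_cockerham(np.array([[40, 0]]), np.array([[40, 0]]))
        assert np.isnan(track.values[0])

    def test_ten_vs_ten_example_matches_component_arithmetic(self):
        track = fst_weir_cockerham(np.array([[20, 18]]), np.array([[20, 2]]))
        assert track.values[0] == pytest.approx(wc_theta_oracle(10, 18, 10, 2), abs=1e-15)
        assert track.values[0] == pytest.approx(599 / 779, abs=1e-12)

    def test_negative_estimates_are_retained(self):
        # nearly identical frequencies at small n give small negative theta
        track = fst_weir_cockerham(np.array([[20, 10]]), np.array([[20, 10]]))
        assert track.values[0] < 0

    def test_mismatched_site_lists_error(self):
        with pytest.raises(ValidationError):
            fst_weir_cockerham(np.array([[20, 1]]), np.array([[20, 1], [20, 2]]))


def _hapset(H, pos=None, chrom="1"):
    H = np.asarray(H, dtype=np.uint8)
    m = H.shape[1]
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    sites = make_site_table([chrom] * m, pos, ["A"] * m, ["C"] * m)
    samples = [f"S{i}" for i in range(H.shape[0] // 2)]
    return HaplotypeSet(
        sites=sites,
        haplotypes=H,
        sample_of_hap=[s for s in samples for _ in range(2)],
        pop_of={s: "pop" for s in samples},
    )


class TestEHH:
    def test_identical_haplotypes_stay_at_one(self):
        H = np.ones((6, 9), dtype=np.uint8)
        left, right = ehh_at_core(H, 4)
        assert np.all(left.ehh == 1.0) and np.all(right.ehh == 1.0)
        assert left.indices[-1] == 0 and right.indices[-1] == 8

    def test_all_distinct_at_first_flank_drops_to_zero(self):
        # two haplotypes differing at the first flanking SNP
        H2 = np.array([[1, 0], [1, 1]], dtype=np.uint8)
        _, right = ehh_at_core(H2, 0)
        assert right.ehh.tolist() == [1.0, 0.0]

    def test_stepwise_class_refinement(self):
        # 4 haplotypes identical at the core; one flank column splits them
        # into two pairs, the next makes all four jointly distinct
        H4 = np.array(
            [[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.uint8
        )
        _, right = ehh_at_core(H4, 0, ehh_cutoff=0.0)
        # classes {2,2}: (1+1)/C(4,2) = 1/3; then all distinct: 0
        assert right.ehh.tolist() == [1.0, pytest.approx(1 / 3), 0.0]

    def test_six_by_eight_fixture_matches_enumeration(self):
        rng = np.random.default_rng(123)
        H = rng.integers(0, 2, size=(6, 8)).astype(np.uint8)
        core = 3
        left, right = ehh_at_core(H, core, ehh_cutoff=0.0)
        exp_left = brute_force_ehh(H, core, "left")
        exp_right = brute_force_ehh(H, core, "right")
        assert list(left.ehh) == exp_left[: len(left.ehh)]
        assert list(right.ehh) == exp_right[: len(right.ehh)]

    def test_fewer_than_two_haplotypes_errors(self):
        with pytest.raises(ValidationError):
            ehh_at_core(np.ones((1, 5), dtype=np.uint8), 2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n_hap=st.integers(2, 12),
        m=st.integers(3, 30),
        core_frac=st.floats(0, 1),
        seed=st.integers(0, 10_000),
    )
    def test_ehh_never_increases_outward(self, n_hap, m, core_frac, seed):
        rng = np.random.default_rng(seed)
        H = rng.integers(0, 2, size=(2 * n_hap, m)).astype(np.uint8)
        core = int(core_frac * (m - 1))
        left, right = ehh_at_core(H, core, ehh_cutoff=0.0)
        for curve in (left, right):
            assert np.all(np.diff(curve.ehh) <= 1e-15)


class TestIHH:
    def _curve(self, side, indices, ehh, snp_id="1:3"):
        d = np.abs(np.arange(len(indices))) * 1000
        return EHHCurve(
            snp_id=snp_id,
            side=side,
            indices=np.asarray(indices),
            distances=d,
            ehh=np.asarray(ehh, dtype=float),
        )

    def test_flat_curve_integrates_to_two_centimorgans(self):
        # EHH == 1 over exactly 1 cM on each side
        pos = np.array([1, 2, 3, 4, 5]) * 10_000
        cm = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        left = self._curve("left", [2, 1, 0], [1, 1, 1])
        right = self._curve("right", [2, 3, 4], [1, 1, 1])
        assert ihh(left, right, pos, cm) == pytest.approx(2.0)

    def test_immediate_drop_gives_first_interval_trapezoid(self):
        pos = np.array([1, 2, 3]) * 10_000
        cm = np.array([0.0, 0.2, 0.4])
        left = self._curve("left", [1, 0], [1, 0])
        right = self._curve("right", [1, 2], [1, 0])
        # each side: 0.5 * (1 + 0) * 0.2 cM
        assert ihh(left, right, pos, cm) == pytest.approx(0.2)

    def test_hand_computed_three_point_curve(self):
        pos = np.array([1, 2, 3, 4, 5]) * 10_000
        cm = np.array([0.0, 0.1, 0.25, 0.3, 0.6])
        left = self._curve("left", [2, 1, 0], [1.0, 0.6, 0.2])
        right = self._curve("right", [2, 3, 4], [1.0, 0.4, 0.04])
        expected = (
            0.5 * (1.0 + 0.6) * (0.25 - 0.1)
            + 0.5 * (0.6 + 0.2) * (0.1 - 0.0)
            + 0.5 * (1.0 + 0.4) * (0.3 - 0.25)
            + 0.5 * (0.4 + 0.04) * (0.6 - 0.3)
        )
        assert ihh(left, right, pos, cm) == pytest.approx(expected, abs=1e-15)

    def test_refining_the_grid_with_interpolated_points_is_invariant(self):
        # inserting a linearly interpolated midpoint must not change the
        # trapezoidal integral of the piecewise-linear curve
        pos = np.array([10_000, 20_000, 30_000])
        cm = np.array([0.0, 0.15, 0.3])
        coarse_r = self._curve("right", [0, 2], [1.0, 0.2])
        fine_r = self._curve("right", [0, 1, 2], [1.0, 0.6, 0.2])  # 0.6 = lerp at cm 0.15
        empty_l = self._curve("left", [0], [1.0])
        coarse = ihh(empty_l, coarse_r, pos, cm)
        fine = ihh(empty_l, fine_r, pos, cm)
        assert abs(coarse - fine) < 1e-12

    def test_large_gap_terminates_integration(self):
        pos = np.array([10_000, 20_000, 400_000])
        cm = pos * 1e-6
        left = self._curve("left", [0], [1.0])
        right = self._curve("right", [0, 1, 2], [1.0, 0.8, 0.6])
        # the 380 kb gap between the 2nd and 3rd point exceeds 200 kb
        expected = 0.5 * (1.0 + 0.8) * (0.02 - 0.01)
        assert ihh(left, right, pos, cm) == pytest.approx(expected)


class TestXPEHH:
    def test_scan_kernel_matches_per_core_curves(self):
        rng = np.random.default_rng(5)
        H = rng.integers(0, 2, size=(20, 60)).astype(np.uint8)
        haps = _hapset(H)
        pos = haps.sites["pos"].to_numpy()
        cm = haps.sites["cm"].to_numpy()
        scanned = ihh_scan(haps)
        for core in range(0, 60, 7):
            left, right = ehh_at_core(haps, core)
            expected = ihh(left, right, pos, cm)
            assert scanned[core] == pytest.approx(expected, abs=1e-12)

    def test_identical_populations_give_zero(self):
        rng = np.random.default_rng(2)
        H = rng.integers(0, 2, size=(30, 80)).astype(np.uint8)
        track = xpehh(_hapset(H), _hapset(H.copy()))
        defined = ~np.isnan(track.values)
        assert defined.any()
        assert np.all(track.values[defined] == 0.0)

    def test_swapping_populations_flips_the_sign_exactly(self, sweep_panel_seed1):
        haps, _ = sweep_panel_seed1
        t = haps.restrict_population("target")
        r = haps.restrict_population("reference")
        ab = xpehh(t, r).values
        ba = xpehh(r, t).values
        defined = ~np.isnan(ab)
        assert np.array_equal(np.isnan(ab), np.isnan(ba))
        assert np.array_equal(ab[defined], -ba[defined])

    def test_peak_localizes_to_the_planted_core(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            haps, truth, _ = simulate_sweep_panel(SweepSimParams(seed=seed))
            track = xpehh(
                haps.restrict_population("target"),
                haps.restrict_population("reference"),
            )
            pos = haps.sites["pos"].to_numpy()
            peak = int(np.nanargmax(np.abs(track.values)))
            if abs(pos[peak] - truth.core_pos_bp) <= 100_000:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_site_mismatch_errors(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, size=(10, 20)).astype(np.uint8)
        a = _hapset(H)
        b = _hapset(H, pos=np.arange(1, 21) * 2000)
        with pytest.raises(ValidationError):
            xpehh(a, b)


class TestDeltaSafAndStandardize:
    def test_equal_frequencies_give_zero_vector(self):
        p = np.linspace(0.1, 0.9, 10)
        assert np.all(delta_saf(p, p).values == 0.0)

    def test_bounds_and_sign_convention(self):
        track = delta_saf(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert track.values.tolist() == [1.0, -1.0]

    def test_undefined_where_either_frequency_undefined(self):
        track = delta_saf(np.array([0.5, np.nan]), np.array([np.nan, 0.5]))
        assert np.isnan(track.values).all()

    def test_standardize_closed_form(self):
        track = SiteStatTrack(np.array(["a", "b", "c"], dtype=object),
                              np.array([1.0, 2.0, 3.0]), "dSAF")
        z = standardize(track)
        assert z.values.tolist() == [-1.0, 0.0, 1.0]  # sample sd = 1

    def test_standardize_constant_vector_errors(self):
        track = SiteStatTrack(np.array(["a", "b"], dtype=object),
                              np.array([2.0, 2.0]), "dSAF")
        with pytest.raises(DataError):
            standardize(track)

    def test_standardize_normalization_contract(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, size=1000)
        values[::17] = np.nan
        z = standardize(SiteStatTrack(
            np.array([f"1:{i}" for i in range(1000)], dtype=object), values, "X"))
        ok = ~np.isnan(z.values)
        assert abs(np.mean(z.values[ok])) < 1e-12
        assert abs(np.std(z.values[ok], ddof=1) - 1.0) < 1e-12
        assert np.array_equal(np.isnan(z.values), np.isnan(values))


def test_null_zxpehh_tail_rate_is_near_gaussian():
    """Under the no-sweep simulator the normalized XP-EHH tail beyond |z|=3
    stays the same order of magnitude as the N(0,1) rate (the log-iHH-ratio
    is mildly heavy-tailed, so an exact Gaussian rate is not expected)."""
    values = []
    for seed in range(4):
        haps, _, _ = simulate_sweep_panel(
            SweepSimParams(seed=seed, sweep_freq_target=0.0, n_sites=25_000)
        )
        z = standardize(
            xpehh(
                haps.restrict_population("target"),
                haps.restrict_population("reference"),
            )
        )
        values.append(z.values)
    v = np.concatenate(values)
    v = v[~np.isnan(v)]
    assert len(v) >= 99_000
    rate = float(np.mean(np.abs(v) > 3))
    assert 0.0009 < rate < 0.009
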