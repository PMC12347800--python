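"""Partitioning, inverse-Boltzmann PMFs, replica statistics, features, regions."""

from math import erf, sqrt, pi

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from membranekit import (
    DensityProfile,
    PMFProfile,
    assign_regions,
    combine_replicas,
    compute_density_profile,
    extract_features,
    logp_contrast,
    partition_coefficient,
    pmf_from_density,
    sample_solute_positions,
    symmetrize_pmf,
    symmetrize_profile,
)
from membranekit.constants import rt

from conftest import TEMP, RT330


def profile_on_grid(values, bin_width, z_box=None, **kw):
    n = len(values)
    z = (np.arange(n) - (n - 1) / 2) * bin_width
    defaults = dict(
        bin_width=bin_width, weighting="number", species="solute",
        n_frames=1, box_area=1.0, z_box=z_box or n * bin_width,
    )
    defaults.update(kw)
    return DensityProfile(z_centers=z, values=np.asarray(values, float), **defaults)


def w_profile(z):
    """Analytic W-shaped PMF: exact minima of -5 kJ/mol at |z| = 1.2, an
    exact central maximum of +2 at z = 0, flat zero beyond |z| = 2."""
    az = np.abs(np.asarray(z, dtype=float))
    out = np.zeros_like(az)
    rim = (az > 1.2) & (az < 2.0)
    out[rim] = -2.5 * (1.0 + np.cos(np.pi * (az[rim] - 1.2) / 0.8))
    core = az <= 1.2
    out[core] = -5.0 + 3.5 * (1.0 + np.cos(np.pi * az[core] / 1.2))
    return out


class TestPartition:
    def test_uniform_profile_logp_zero(self):
        prof = profile_on_grid(np.ones(8001), 0.001, z_box=8.001)
        res = partition_coefficient(prof, 3.0)
        assert res.p_memb_bulk == pytest.approx(1.0, abs=1e-12)
        assert res.logp == 0.0

    def test_piecewise_linear_closed_form(self):
        # ramp profile: 2c inside |z| < 1.5 - bw, c outside |z| > 1.5 + bw,
        # linear in between; closed-form integrals computed by hand
        bw = 0.01
        c = 0.7
        z_box = 8.0
        n = int(z_box / bw) // 2 * 2 + 1
        z = (np.arange(n) - (n - 1) / 2) * bw
        v = np.where(np.abs(z) <= 1.5 - bw, 2 * c,
                     np.where(np.abs(z) >= 1.5 + bw, c, np.nan))
        ramp = np.isnan(v)
        v[ramp] = c * (1.0 + (1.5 + bw - np.abs(z[ramp])) / (2 * bw))
        prof = profile_on_grid(v, bw, z_box=z_box)
        dhh = 3.0
        # exact piecewise-linear integrals (cut at 1.5 sits mid-ramp, 1.5c):
        #   core [0, 1.5-bw]: 2c(1.5-bw); ramp [1.5-bw, 1.5]: (2c+1.5c)/2*bw
        i_memb = 2 * (2 * c * (1.5 - bw) + 1.75 * c * bw)
        # ramp [1.5, 1.5+bw]: (1.5c+c)/2*bw; tail [1.5+bw, 4]: c*(2.5-bw)
        i_bulk = 2 * (1.25 * c * bw + c * (2.5 - bw))
        p_expected = (i_memb / dhh) / (i_bulk / (z_box - dhh))
        res = partition_coefficient(prof, dhh)
        assert res.p_memb_bulk == pytest.approx(p_expected, rel=1e-9)

    def test_gaussian_enrichment_closed_form(self):
        bw = 0.001
        c, amp, s = 1.0, 3.0, 0.7
        z_box, dhh = 8.0, 3.0
        n = int(z_box / bw) // 2 * 2 + 1
        z = (np.arange(n) - (n - 1) / 2) * bw
        prof = profile_on_grid(c + amp * np.exp(-z**2 / (2 * s**2)), bw, z_box=z_box)

        def gauss_int(a, b):
            return c * (b - a) + amp * s * sqrt(pi / 2) * (
                erf(b / (s * sqrt(2))) - erf(a / (s * sqrt(2)))
            )

        i_memb = gauss_int(-dhh / 2, dhh / 2)
        i_tot = gauss_int(-z_box / 2, z_box / 2)
        expected = (i_memb / dhh) / ((i_tot - i_memb) / (z_box - dhh))
        res = partition_coefficient(prof, dhh)
        assert res.p_memb_bulk == pytest.approx(expected, rel=1e-6)

    def test_no_bulk_solute_raises(self):
        v = np.where(np.abs((np.arange(801) - 400) * 0.01) < 1.0, 1.0, 0.0)
        prof = profile_on_grid(v, 0.01, z_box=8.01)
        with pytest.raises(ValueError, match="no solute in bulk"):
            partition_coefficient(prof, 6.0)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(0.1, 100.0))
    def test_invariance_under_uniform_scaling(self, scale):
        rng = np.random.default_rng(7)
        v = rng.uniform(0.5, 2.0, 401)
        a = partition_coefficient(profile_on_grid(v, 0.02), 3.0).p_memb_bulk
        b = partition_coefficient(profile_on_grid(scale * v, 0.02), 3.0).p_memb_bulk
        assert b == pytest.approx(a, rel=1e-9)

    def test_integral_partition(self):
        rng = np.random.default_rng(3)
        prof = profile_on_grid(rng.uniform(0.1, 1.0, 401), 0.02)
        res = partition_coefficient(prof, 3.0)
        total = res.membrane_integral + res.bulk_integral
        i_total = np.trapezoid(
            np.concatenate([[prof.values[0]], prof.values, [prof.values[-1]]]),
            np.concatenate([[-prof.z_box / 2], prof.z_centers, [prof.z_box / 2]]),
        )
        assert total == pytest.approx(i_total, rel=1e-9)


class TestLogPContrast:
    def test_equal_inputs_zero(self):
        assert logp_contrast(-0.5, -0.5) == 0.0

    def test_dioxane_membrane_contrast(self):
        # |logP| drops from 0.55 (PE bilayer) to 0.20 (PG bilayer)
        assert logp_contrast(-0.20, -0.55) == pytest.approx(63.7, abs=0.2)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-5, 5), st.floats(0.01, 5))
    def test_sign_flip_invariance(self, a, b):
        assert logp_contrast(-a, -b) == pytest.approx(logp_contrast(a, b))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            logp_contrast(1.0, 0.0)


class TestInverseBoltzmann:
    def test_reference_density_gives_zero(self):
        prof = profile_on_grid(np.full(41, 2.5), 0.1)
        pmf = pmf_from_density(prof, 2.5, TEMP)
        np.testing.assert_allclose(pmf.values, 0.0, atol=1e-12)

    def test_doubled_density_closed_form(self):
        v = np.ones(41)
        v[20] = 2.0
        pmf = pmf_from_density(profile_on_grid(v, 0.1), 1.0, 330.0)
        assert pmf.values[20] == pytest.approx(-8.314462618e-3 * 330 * np.log(2),
                                               rel=1e-9)
        assert pmf.values[20] == pytest.approx(-1.902, abs=0.001)

    def test_zero_bins_masked_not_clamped(self):
        v = np.ones(41)
        v[5] = 0.0
        pmf = pmf_from_density(profile_on_grid(v, 0.1), 1.0, TEMP)
        assert not pmf.mask[5]
        assert np.isnan(pmf.values[5])

    def test_round_trip_density(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.2, 3.0, 41)
        rho0 = 1.3
        pmf = pmf_from_density(profile_on_grid(v, 0.1), rho0, TEMP)
        back = rho0 * np.exp(-pmf.values / RT330)
        np.testing.assert_allclose(back, v, rtol=1e-12)

    def test_sampled_double_well_rmse(self):
        # generator round trip at n = 1e6 against the analytic potential
        lo, hi = -2.6, 2.6
        n = 1_000_000
        z = sample_solute_positions(w_profile, (lo, hi), n, TEMP, seed=4)
        bw = 0.02
        nbins = int((hi - lo) / bw) // 2 * 2 + 1
        centers = (np.arange(nbins) - (nbins - 1) / 2) * bw
        edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])
        cnt, _ = np.histogram(z, edges)
        prof = profile_on_grid(cnt / (bw * n), bw, z_box=hi - lo)
        pmf = pmf_from_density(prof, 1.0, TEMP, bulk_z=2.2)
        sel = (cnt >= 100) & pmf.mask
        ref = w_profile(centers)
        ref = ref - ref[np.abs(centers) > 2.2].mean()
        rmse = np.sqrt(np.mean((pmf.values[sel] - ref[sel]) ** 2))
        assert rmse < 0.3

    def test_symmetrize_commutes_for_symmetric_density(self):
        rng = np.random.default_rng(5)
        half = rng.uniform(0.5, 2.0, 20)
        v = np.concatenate([half, [1.7], half[::-1]])
        prof = profile_on_grid(v, 0.1)
        a = pmf_from_density(symmetrize_profile(prof), 1.0, TEMP)
        b = symmetrize_pmf(pmf_from_density(prof, 1.0, TEMP))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)


class TestSymmetrizePMF:
    def make_pmf(self, values, mask=None):
        n = len(values)
        z = (np.arange(n) - (n - 1) / 2) * 0.1
        return PMFProfile(z=z, values=np.asarray(values, float),
                          temperature=TEMP, mask=mask)

    def test_even_input_unchanged(self):
        v = np.abs(np.arange(-5, 6)).astype(float)
        out = symmetrize_pmf(self.make_pmf(v))
        np.testing.assert_allclose(out.values, v)

    def test_one_sided_propagation(self):
        v = np.full(11, np.nan)
        v[8] = 3.0
        out = symmetrize_pmf(self.make_pmf(v))
        assert out.values[8] == 3.0
        assert out.values[2] == 3.0
        assert out.one_sided[2] and out.one_sided[8]

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=21)
        once = symmetrize_pmf(self.make_pmf(v))
        twice = symmetrize_pmf(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)


class TestCombineReplicas:
    def make(self, values):
        n = len(values)
        z = (np.arange(n) - (n - 1) / 2) * 0.1
        return PMFProfile(z=z, values=np.asarray(values, float), temperature=TEMP)

    def test_identical_replicas_zero_sd(self):
        v = np.arange(11.0)
        out = combine_replicas([self.make(v), self.make(v)])
        np.testing.assert_allclose(out.sd[out.mask], 0.0)

    def test_two_point_statistics(self):
        v = np.zeros(11)
        w = np.zeros(11)
        w[4] = 1.0
        out = combine_replicas([self.make(v), self.make(w)])
        assert out.values[4] == pytest.approx(0.5)
        assert out.sd[4] == pytest.approx(1 / np.sqrt(2))

    def test_grid_mismatch_rejected(self):
        a = self.make(np.zeros(11))
        b = PMFProfile(z=a.z + 0.05, values=np.zeros(11), temperature=TEMP)
        with pytest.raises(ValueError, match="grids"):
            combine_replicas([a, b])

    def test_replica_sd_consistent_with_counting_noise(self):
        # replicas from the same generator: observed inter-replica sd should
        # match the multinomial propagation estimate within a factor of 2
        lo, hi, bw, n = -2.6, 2.6, 0.05, 200_000
        nbins = int((hi - lo) / bw) // 2 * 2 + 1
        centers = (np.arange(nbins) - (nbins - 1) / 2) * bw
        edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])
        pmfs = []
        counts = []
        for seed in (10, 11, 12, 13):
            z = sample_solute_positions(w_profile, (lo, hi), n, TEMP, seed=seed)
            cnt, _ = np.histogram(z, edges)
            counts.append(cnt)
            prof = profile_on_grid(cnt / (bw * n), bw, z_box=hi - lo)
            pmfs.append(pmf_from_density(prof, 1.0, TEMP, bulk_z=2.2))
        out = combine_replicas(pmfs)
        mean_cnt = np.mean(counts, axis=0)
        sel = mean_cnt > 200
        predicted = RT330 / np.sqrt(mean_cnt[sel])  # delta-method per replica
        ratio = np.median(out.sd[sel] / predicted)
        assert 0.5 < ratio < 2.0


class TestFeatures:
    def grid_pmf(self, fn, bw=0.02, half=2.6):
        n = int(2 * half / bw) // 2 * 2 + 1
        z = (np.arange(n) - (n - 1) / 2) * bw
        return PMFProfile(z=z, values=fn(z), temperature=TEMP)

    def test_w_profile_exact_extrema(self):
        pmf = self.grid_pmf(w_profile)
        feats = extract_features(pmf, dhh=3.8, smoothing_window=1)
        assert feats.central_barrier_vs_bulk == pytest.approx(2.0, abs=1e-9)
        assert feats.central_barrier_vs_adjacent_min == pytest.approx(7.0, abs=1e-9)
        assert feats.central_barrier_position == pytest.approx(0.0, abs=1e-12)
        depths = sorted((pos, d) for pos, d in feats.minima)
        assert any(abs(p + 1.2) < 1e-9 and abs(d + 5.0) < 1e-9 for p, d in depths)
        assert any(abs(p - 1.2) < 1e-9 and abs(d + 5.0) < 1e-9 for p, d in depths)

    def test_flat_profile_has_no_features(self):
        pmf = self.grid_pmf(lambda z: np.zeros_like(z))
        feats = extract_features(pmf, dhh=3.8)
        assert feats.central_barrier_vs_bulk is None
        assert feats.outer_barrier is None
        assert feats.minima == ()

    def test_sampled_w_profile_features(self):
        lo, hi, n = -2.6, 2.6, 1_000_000
        z = sample_solute_positions(w_profile, (lo, hi), n, TEMP, seed=6)
        bw = 0.02
        nbins = int((hi - lo) / bw) // 2 * 2 + 1
        centers = (np.arange(nbins) - (nbins - 1) / 2) * bw
        edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])
        cnt, _ = np.histogram(z, edges)
        prof = profile_on_grid(cnt / (bw * n), bw, z_box=hi - lo)
        pmf = pmf_from_density(prof, 1.0, TEMP, bulk_z=2.2)
        feats = extract_features(pmf, dhh=3.8, smoothing_window=5)
        assert feats.central_barrier_vs_bulk == pytest.approx(2.0, abs=0.3)
        assert feats.central_barrier_position == pytest.approx(0.0, abs=0.05)
        inner = [m for m in feats.minima if 0.5 < abs(m[0]) < 2.0]
        assert inner
        pos, depth = min(inner, key=lambda m: m[1])
        assert depth == pytest.approx(-5.0, abs=0.3)
        assert abs(abs(pos) - 1.2) < 0.05

    def test_width_at_half_height(self):
        # triangle barrier of height 4 over flanking minima at 0, half
        # height 2 reached at |z| = 0.5 exactly
        def tri(z):
            return np.maximum(4.0 - 4.0 * np.abs(z), 0.0)

        pmf = self.grid_pmf(tri, bw=0.05, half=2.0)
        feats = extract_features(pmf, dhh=4.0, smoothing_window=1)
        assert feats.central_barrier_width == pytest.approx(1.0, abs=1e-9)


class TestRegions:
    def make_profiles(self):
        bw = 0.05
        n = 121  # spans +/- 3 nm
        z = (np.arange(n) - (n - 1) / 2) * bw
        head = np.exp(-((np.abs(z) - 1.9) ** 2) / (2 * 0.15**2))
        lipid = 1.0 / (1.0 + np.exp((np.abs(z) - 2.1) / 0.05))
        water = 1.0 - lipid
        kw = dict(bin_width=bw, n_frames=1, box_area=1.0, z_box=n * bw)
        return (
            DensityProfile(z_centers=z, values=lipid, weighting="mass",
                           species="lipid", **kw),
            DensityProfile(z_centers=z, values=water, weighting="mass",
                           species="water", **kw),
            DensityProfile(z_centers=z, values=head, weighting="electron",
                           species="headgroup", **kw),
        )

    def test_constructed_boundaries(self):
        lipid, water, head = self.make_profiles()
        regions = assign_regions(lipid, water, head, dhh=3.8)
        assert regions.region_iv == (0.0, pytest.approx(0.95))
        assert regions.region_ii[1] == pytest.approx(2.1, abs=0.05)
        assert regions.region_i[1] - regions.region_i[0] == pytest.approx(0.5)
        # headgroup inner edge: peak - sqrt(2 ln 10) sigma ~ 1.58
        assert regions.region_iii[1] == pytest.approx(1.58, abs=0.05)

    def test_headgroup_peak_inside_region_ii(self, small_ensemble):
        lipid = compute_density_profile(small_ensemble, "lipid", "mass", 0.1)
        water = compute_density_profile(small_ensemble, "water", "mass", 0.1)
        head = compute_density_profile(small_ensemble, "headgroup", "electron", 0.1)
        regions = assign_regions(lipid, water, head, dhh=3.732)
        zpeak = abs(head.z_centers[np.argmax(head.values)])
        assert regions.locate(zpeak) == "II"

    def test_water_only_system_rejected(self):
        lipid, water, head = self.make_profiles()
        from dataclasses import replace
        no_lipid = replace(lipid, values=np.zeros_like(lipid.values))
        with pytest.raises(ValueError, match="not resolved"):
            assign_regions(no_lipid, water, head, dhh=3.8)
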