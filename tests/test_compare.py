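"""Group comparison: per-individual densities, rank-sum maps, orbits."""

import warnings

import numpy as np
import pytest

from posturemap import compare as cmp
from posturemap import phase as ph
from posturemap.behaviormap import estimate_density


def _cohort_z(rng, n_ind, centers, weights, n_frames=1200, spread=0.6):
    """Individuals sampled from a shared mixture of 2D bumps."""
    out = []
    for _ in range(n_ind):
        comp = rng.choice(len(centers), size=n_frames, p=weights)
        z = np.asarray(centers)[comp] + rng.normal(0, spread, (n_frames, 2))
        out.append(z)
    return out


CENTERS = [(0.0, 0.0), (6.0, 0.0), (0.0, 6.0), (6.0, 6.0)]
W_NULL = [0.25, 0.25, 0.25, 0.25]


class TestPerIndividualDensity:
    def test_identical_individuals_zero_difference(self):
        rng = np.random.default_rng(0)
        z = _cohort_z(rng, 1, CENTERS, W_NULL)[0]
        dset = cmp.per_individual_density(
            [z, z.copy(), z, z.copy()], ["a", "a", "b", "b"], sigma=0.5,
            grid_size=101,
        )
        np.testing.assert_allclose(dset.difference_map("a", "b"), 0.0, atol=1e-15)

    def test_group_mean_is_mixture_of_individuals(self):
        rng = np.random.default_rng(1)
        zs = [np.tile(c, (500, 1)) + rng.normal(0, 0.05, (500, 2))
              for c in CENTERS[:3]]
        dset = cmp.per_individual_density(
            zs, ["a", "a", "a"], sigma=0.4, grid_size=121,
            extent=(-3, 9, -3, 9),
        )
        gm = dset.group_mean("a")
        manual = np.mean([d.grid for d in dset.densities], axis=0)
        np.testing.assert_allclose(gm, manual)
        dx, dy = dset.densities[0].cell_size
        assert gm.sum() * dx * dy == pytest.approx(1.0, abs=1e-3)

    def test_short_individuals_excluded(self):
        rng = np.random.default_rng(2)
        zs = _cohort_z(rng, 4, CENTERS, W_NULL)
        zs.append(rng.normal(0, 1, (3, 2)))  # too short
        with pytest.warns(UserWarning):
            dset = cmp.per_individual_density(
                zs, ["a", "a", "b", "b", "b"], sigma=0.5, grid_size=81
            )
        assert len(dset.densities) == 4

    def test_split_half_intra_vs_inter(self):
        # halves of the same individual are closer than different
        # individuals on an individualized cohort
        rng = np.random.default_rng(3)
        intra, inter = [], []
        base = np.array(CENTERS)
        for trial in range(6):
            # each individual has its own preferred mixture weights
            w1 = rng.dirichlet(np.ones(4) * 5)
            w2 = rng.dirichlet(np.ones(4) * 5)
            z1 = _cohort_z(rng, 1, base, w1, n_frames=4000)[0]
            z2 = _cohort_z(rng, 1, base, w2, n_frames=4000)[0]
            ext = (-3, 9, -3, 9)
            d1a = estimate_density(z1[:2000], 0.5, 81, ext).grid
            d1b = estimate_density(z1[2000:], 0.5, 81, ext).grid
            d2a = estimate_density(z2[:2000], 0.5, 81, ext).grid
            intra.append(np.abs(d1a - d1b).sum())
            inter.append(np.abs(d1a - d2a).sum())
        assert np.mean(intra) < np.mean(inter)


class TestRegionNormalized:
    def test_full_mask_unchanged(self):
        rng = np.random.default_rng(4)
        den = estimate_density(rng.normal(0, 1, (2000, 2)), 0.5, 81)
        out = cmp.region_normalized_pdf(den, np.ones_like(den.grid, dtype=bool))
        np.testing.assert_allclose(out.grid, den.grid, rtol=1e-12)

    def test_quarter_mass_scaled_four_times(self):
        rng = np.random.default_rng(5)
        den = estimate_density(rng.normal(0, 1, (20000, 2)), 0.4, 160)
        # mask holding some mass m scales interior values by 1/m
        mask = np.zeros_like(den.grid, dtype=bool)
        mask[:, : mask.shape[1] // 2] = True
        dx, dy = den.cell_size
        m = den.grid[mask].sum() * dx * dy
        out = cmp.region_normalized_pdf(den, mask)
        np.testing.assert_allclose(out.grid[mask], den.grid[mask] / m, rtol=1e-9)
        assert np.all(out.grid[~mask] == 0)

    def test_zero_mass_errors(self):
        rng = np.random.default_rng(6)
        # wide explicit extent leaves the far corner truly at zero density
        den = estimate_density(
            rng.normal(0, 0.1, (500, 2)), 0.2, 81, extent=(-10, 10, -10, 10)
        )
        mask = np.zeros_like(den.grid, dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            cmp.region_normalized_pdf(den, mask)


class TestSignificanceMap:
    def test_disjoint_supports_flagged(self):
        rng = np.random.default_rng(7)
        za = [rng.normal(0, 0.5, (800, 2)) for _ in range(5)]
        zb = [rng.normal(8, 0.5, (800, 2)) for _ in range(5)]
        dset = cmp.per_individual_density(
            za + zb, ["a"] * 5 + ["b"] * 5, sigma=0.3, grid_size=101,
            extent=(-3, 11, -3, 11),
        )
        res = cmp.wilcoxon_significance_map(dset, alpha=0.05)
        # cells dominated by either bump are overwhelmingly flagged
        A = dset.stack("a").mean(axis=0)
        B = dset.stack("b").mean(axis=0)
        core = (A > 0.2 * A.max()) | (B > 0.2 * B.max())
        assert res.mask[core & res.testable].mean() > 0.95

    def test_group_effect_localizes(self):
        # group b has an extra bump; individuals vary in their weights on
        # the shared bumps, so only the extra-bump neighbourhood separates
        rng = np.random.default_rng(8)

        def individuals(n, extra):
            out = []
            for _ in range(n):
                w3 = rng.dirichlet([20.0, 20.0, 20.0])
                if extra:
                    w = np.concatenate([w3 * (1 - 0.16), [0.16]])
                    out.append(_cohort_z(rng, 1, CENTERS, w, n_frames=3000)[0])
                else:
                    out.append(_cohort_z(rng, 1, CENTERS[:3], w3, n_frames=3000)[0])
            return out

        za = individuals(8, extra=False)
        zb = individuals(8, extra=True)
        dset = cmp.per_individual_density(
            za + zb, ["a"] * 8 + ["b"] * 8, sigma=0.4, grid_size=101,
            extent=(-3, 9, -3, 9),
        )
        res = cmp.wilcoxon_significance_map(dset, alpha=0.01)
        xs = np.linspace(-3, 9, 101)
        X, Y = np.meshgrid(xs, xs)
        near_new = np.hypot(X - 6, Y - 6) < 1.5
        far = np.hypot(X - 0, Y - 0) < 1.5
        assert res.mask[near_new & res.testable].mean() > 0.5
        assert res.mask[far & res.testable].mean() < 0.2

    def test_label_permutation_restores_null(self):
        rng = np.random.default_rng(9)
        za = _cohort_z(rng, 6, CENTERS[:3], [1 / 3] * 3, n_frames=2500)
        zb = _cohort_z(rng, 6, CENTERS, [0.28, 0.28, 0.28, 0.16], n_frames=2500)
        zs = za + zb
        labels = np.array(["a"] * 6 + ["b"] * 6)
        dset = cmp.per_individual_density(zs, labels, sigma=0.4, grid_size=81,
                                          extent=(-3, 9, -3, 9))
        res_true = cmp.wilcoxon_significance_map(dset, alpha=0.01)
        perm = labels.copy()
        rng.shuffle(perm)
        dperm = cmp.IndividualDensitySet(
            densities=dset.densities, groups=perm,
            extent=dset.extent, sigma=dset.sigma,
        )
        res_perm = cmp.wilcoxon_significance_map(dperm, alpha=0.01)
        frac_true = res_true.mask.sum() / max(res_true.testable.sum(), 1)
        frac_perm = res_perm.mask.sum() / max(res_perm.testable.sum(), 1)
        assert frac_perm < 0.05
        assert frac_perm < frac_true

    def test_needs_three_per_group(self):
        rng = np.random.default_rng(10)
        zs = _cohort_z(rng, 4, CENTERS, W_NULL)
        dset = cmp.per_individual_density(zs, ["a", "a", "b", "b"], sigma=0.5,
                                          grid_size=61)
        with pytest.raises(ValueError):
            cmp.wilcoxon_significance_map(dset)

    def test_fdr_mask_is_subset(self):
        rng = np.random.default_rng(11)
        za = [rng.normal(0, 0.6, (700, 2)) for _ in range(5)]
        zb = [rng.normal(1.2, 0.6, (700, 2)) for _ in range(5)]
        dset = cmp.per_individual_density(
            za + zb, ["a"] * 5 + ["b"] * 5, sigma=0.4, grid_size=81,
        )
        res = cmp.wilcoxon_significance_map(dset, alpha=0.01)
        assert not (res.fdr_mask & ~res.mask).any()


def _orbit_bouts(f, n, rng, amp=(1.0, 1.0), T_s=2.0, noise=0.05, fs=100.0):
    bouts = []
    for i in range(n):
        t = np.arange(0, T_s, 1 / fs)
        phi0 = rng.uniform(0, 2 * np.pi)
        y = np.vstack(
            [amp[0] * np.cos(2 * np.pi * f * t + phi0),
             amp[1] * np.sin(2 * np.pi * f * t + phi0)]
        ) + rng.normal(0, noise, (2, len(t)))
        bouts.append((y, ph.reconstruct_phase(y, fs)))
    return bouts


class TestGroupOrbits:
    def test_same_generator_no_separation(self):
        rng = np.random.default_rng(12)
        a = _orbit_bouts(8.0, 10, rng)
        b = _orbit_bouts(8.0, 10, rng)
        oa, ob, sep, fd, fse = cmp.compare_group_orbits(a, b)
        assert sep.mean() < 0.2
        assert abs(fd) <= 3 * max(fse, 1e-3)

    def test_amplitude_scaled_mode_flagged(self):
        rng = np.random.default_rng(13)
        a = _orbit_bouts(8.0, 12, rng, amp=(1.5, 1.0))
        b = _orbit_bouts(8.0, 12, rng, amp=(1.0, 1.0))
        oa, ob, sep, fd, fse = cmp.compare_group_orbits(a, b)
        assert sep[0].mean() > 0.5  # scaled mode separates
        assert abs(fd) < 0.25  # frequency consistent between groups

    def test_frequency_shift_detected_without_shape_flags(self):
        rng = np.random.default_rng(14)
        a = _orbit_bouts(8.0, 12, rng)
        b = _orbit_bouts(9.6, 12, rng)
        oa, ob, sep, fd, fse = cmp.compare_group_orbits(a, b)
        assert abs(fd) == pytest.approx(1.6, abs=0.3)
        assert abs(fd) > 4 * fse
        # same circular orbit shape: separation at near-chance level
        assert sep.mean() < 0.3

    def test_insufficient_bouts(self):
        rng = np.random.default_rng(15)
        a = _orbit_bouts(8.0, 3, rng)
        b = _orbit_bouts(8.0, 6, rng)
        with pytest.raises(ValueError):
            cmp.compare_group_orbits(a, b)
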